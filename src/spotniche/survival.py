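"""Surface-candidate prioritization funnel and from-scratch survival statistics.

The funnel intersects differential-expression hits, aberrant-splicing hits,
and pseudotime-dynamic genes, cross-references a surfaceome list, and keeps
only candidates whose high expression is *adverse* for survival: the
Kaplan-Meier product-limit estimator and the two-group log-rank test are
implemented here from first principles.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .datatypes import KMCurve, SurvivalTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- funnel

def deg_filter(
    stats: pd.DataFrame,
    p_max: float = 0.05,
    abs_logfc_min: float = 1.2,
    direction: str = "up",
) -> set[str]:
    """Differential-expression filter with strict inequalities.

    Keeps genes with p < p_max and log_fc > abs_logfc_min (direction "up"),
    log_fc < -abs_logfc_min ("down"), or |log_fc| > abs_logfc_min ("both").
    Boundary rows (p exactly p_max or |log_fc| exactly the cutoff) are
    excluded — the filters are strict.
    """
    for col in ("gene", "p_value", "log_fc"):
        if col not in stats.columns:
            raise ValueError(f"stats table missing column {col!r}")
    if stats.empty:
        raise ValueError("empty statistics table")
    p = stats["p_value"].to_numpy(dtype=float)
    lfc = stats["log_fc"].to_numpy(dtype=float)
    keep = p < p_max
    if direction == "up":
        keep &= lfc > abs_logfc_min
    elif direction == "down":
        keep &= lfc < -abs_logfc_min
    elif direction == "both":
        keep &= np.abs(lfc) > abs_logfc_min
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return set(stats.loc[keep, "gene"].astype(str))


def intersect_funnel(
    deg_sets: Sequence[set[str]],
    as_set: set[str],
    pseudotime_set: set[str],
    surfaceome_set: set[str],
) -> pd.DataFrame:
    """Set-algebra funnel with per-gene provenance flags.

    Multiple DEG sets are intersected first (shared hits across cohorts),
    then intersected with splicing hits, pseudotime-dynamic genes, and the
    surfaceome list. Empty inputs yield an empty result with a warning
    rather than an error. Returns one row per gene in the union of all
    inputs with boolean provenance flags and a ``in_funnel`` column.
    """
    deg_sets = [set(s) for s in deg_sets]
    stages: dict[str, set[str]] = {
        "deg": set.intersection(*deg_sets) if deg_sets else set(),
        "as_hit": set(as_set),
        "pseudotime_dynamic": set(pseudotime_set),
        "surfaceome": set(surfaceome_set),
    }
    for name, s in stages.items():
        if not s:
            log.warning("funnel stage %r is empty; result will be empty", name)
    universe = sorted(set().union(*stages.values()))
    df = pd.DataFrame({"gene": universe})
    for name, s in stages.items():
        df[name] = df["gene"].isin(s)
    df["in_funnel"] = df[list(stages)].all(axis=1)
    return df


# ------------------------------------------------------------ KM / logrank

def km_estimate(table: SurvivalTable) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i); the median is
    the smallest time at which S(t) <= 0.5 (nan if never reached). With no
    events the curve is flat at 1.
    """
    order = np.argsort(table.time, kind="stable")
    t = table.time[order]
    e = table.event[order]
    event_times = np.unique(t[e])
    n_at_risk = np.array([(t >= et).sum() for et in event_times], dtype=int)
    n_events = np.array([((t == et) & e).sum() for et in event_times], dtype=int)
    if len(event_times) == 0:
        return KMCurve(
            times=np.array([]), survival=np.array([]),
            n_at_risk=np.array([], dtype=int), n_events=np.array([], dtype=int),
            median=float("nan"),
        )
    surv = np.cumprod(1.0 - n_events / n_at_risk)
    below = surv <= 0.5
    median = float(event_times[np.argmax(below)]) if below.any() else float("nan")
    return KMCurve(
        times=event_times, survival=surv, n_at_risk=n_at_risk,
        n_events=n_events, median=median,
    )


def logrank_test(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> dict:
    """Two-group log-rank test (1 df).

    At each pooled event time, the observed events in group 1 are compared
    with the hypergeometric expectation given the margins; the statistic is
    (O - E)^2 / V against chi-square(1). ``direction`` is the sign of
    (O - E) for the group labelled True/1/"high": positive means that group
    dies faster than expected (adverse).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    g1 = group == levels[-1]  # the "high" group: True, 1, or lexicographically last
    if g1.sum() == 0 or (~g1).sum() == 0:
        raise ValueError("each group needs >= 1 subject")
    event_times = np.unique(time[event])
    if len(event_times) == 0:
        raise ValueError("no events in either group")
    O = E = V = 0.0
    for et in event_times:
        at_risk = time >= et
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = (event & (time == et)).sum()
        d1 = (event & (time == et) & g1).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return {"statistic": 0.0, "p_value": 1.0, "direction": "none", "o_minus_e": 0.0}
    stat = (O - E) ** 2 / V
    return {
        "statistic": float(stat),
        "p_value": float(chi2.sf(stat, df=1)),
        "direction": "adverse" if O > E else ("protective" if O < E else "none"),
        "o_minus_e": float(O - E),
    }


# ------------------------------------------------------- survival filter

def survival_filter(
    candidates: Iterable[str],
    expression: pd.DataFrame,
    survival: SurvivalTable | Mapping[str, SurvivalTable],
    p_max: float = 0.05,
    quantile: float = 0.5,
) -> pd.DataFrame:
    """Keep candidates whose high expression is significantly adverse.

    Per gene: dichotomize samples at the ``quantile`` of expression
    (default median), run the log-rank test, and retain the gene iff
    p < p_max (strict) *and* the high-expression group has more observed
    than expected events (adverse direction). ``expression`` is genes x
    samples. In multi-cohort mode (a mapping of cohort name -> table with a
    matching expression frame per cohort is not needed — the same frame is
    subset by sample ids) the criterion must hold in every cohort.
    """
    cohorts = (
        {"cohort": survival} if isinstance(survival, SurvivalTable) else dict(survival)
    )
    rows = []
    for gene in candidates:
        if gene not in expression.index:
            raise KeyError(f"gene {gene!r} missing from expression table")
        retained = True
        worst_p, direction = 0.0, "adverse"
        for name, surv in cohorts.items():
            missing = [s for s in surv.sample_ids if s not in expression.columns]
            if missing:
                raise ValueError(f"cohort {name}: samples missing from expression: {missing[:3]}")
            vals = expression.loc[gene, list(surv.sample_ids)].to_numpy(dtype=float)
            if np.ptp(vals) == 0:
                raise ValueError(f"gene {gene!r}: constant expression in cohort {name}")
            thr = np.quantile(vals, quantile)
            high = vals > thr
            res = logrank_test(surv.time, surv.event, high)
            worst_p = max(worst_p, res["p_value"])
            if res["direction"] != "adverse" or not res["p_value"] < p_max:
                retained = False
                direction = res["direction"]
        rows.append(
            {
                "gene": gene,
                "survival_p": worst_p,
                "direction": direction,
                "retained": retained,
            }
        )
    return pd.DataFrame(rows)


def prioritize(
    deg_tables: Sequence[pd.DataFrame],
    as_set: set[str],
    pseudotime_set: set[str],
    surfaceome_set: set[str],
    expression: pd.DataFrame,
    survival: SurvivalTable | Mapping[str, SurvivalTable],
    p_max_deg: float = 0.05,
    abs_logfc_min: float = 1.2,
    p_max_survival: float = 0.05,
) -> pd.DataFrame:
    """Full candidate funnel: DEG thresholds -> set intersections ->
    surfaceome cross-reference -> survival-based filtering."""
    deg_sets = [deg_filter(t, p_max_deg, abs_logfc_min) for t in deg_tables]
    funnel = intersect_funnel(deg_sets, as_set, pseudotime_set, surfaceome_set)
    shortlist = funnel.loc[funnel["in_funnel"], "gene"].tolist()
    if not shortlist:
        funnel["survival_p"] = np.nan
        funnel["direction"] = ""
        funnel["retained"] = False
        return funnel
    surv_df = survival_filter(shortlist, expression, survival, p_max=p_max_survival)
    out = funnel.merge(surv_df, on="gene", how="left")
    out["retained"] = out["retained"].astype("boolean").fillna(False).astype(bool) & out["in_funnel"]
    return out
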