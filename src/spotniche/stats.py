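"""Bivariate spatial association statistics and nonparametric rank tests.

Implemented from first principles:

* bivariate global Moran's I with a Monte-Carlo permutation test
  (permute y, hold x and the weights fixed),
* bivariate LISA with HH/HL/LH/LL quadrant labels and conditional
  permutation p-values, Benjamini-Hochberg adjusted across spots,
* Mann-Whitney / Wilcoxon rank-sum and Wilcoxon signed-rank tests with
  exact enumeration branches for small samples and tie-corrected,
  continuity-corrected normal approximations otherwise.

Normalization convention: both variables are z-scored with the population
standard deviation and the weight matrix is row-standardized, with a 1/n
prefactor, so that (a) mean(local I) equals global I exactly and (b) a
perfectly anti-aligned two-spot pair gives I = -1.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    MoranResult,
    RankTestResult,
    ScoreVector,
    SpotLattice,
    StratumLabels,
    WeightMatrix,
)
from .graph import min_distance_to_set


# ---------------------------------------------------------------- moran

def standardize(values: np.ndarray, ddof: int = 0) -> np.ndarray:
    """z-scores: mean 0, SD 1 (population SD by default)."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("constant vector cannot be standardized")
    return (v - v.mean()) / sd


def _check_standardized(z: np.ndarray, name: str) -> None:
    if abs(z.mean()) > 1e-6 or abs(z.std(ddof=0) - 1) > 1e-6:
        raise ValueError(f"{name} is not standardized (mean 0, population SD 1)")


def bivariate_moran(z_x: np.ndarray, z_y: np.ndarray, W: WeightMatrix) -> float:
    """I = (1/n) sum_i z_x,i * sum_j w_ij z_y,j.

    Positive I: high x co-locates with high y in the neighborhood.
    """
    z_x = np.asarray(z_x, dtype=float)
    z_y = np.asarray(z_y, dtype=float)
    if len(z_x) != len(z_y) or len(z_x) != W.n:
        raise ValueError("length mismatch among z_x, z_y, W")
    _check_standardized(z_x, "z_x")
    _check_standardized(z_y, "z_y")
    if not W.row_standardized:
        raise ValueError("W must be row-standardized for this normalization")
    return float(z_x @ W.lag(z_y) / W.n)


def moran_mc_test(
    x: np.ndarray,
    y: np.ndarray,
    W: WeightMatrix,
    n_perm: int = 999,
    alternative: str = "greater",
    seed: int = 0,
) -> MoranResult:
    """Monte-Carlo permutation test for bivariate Moran's I.

    y's values are randomly reassigned across spots ``n_perm`` times while x
    and W stay fixed; p = (1 + b) / (n_perm + 1) where b counts permuted
    statistics as or more extreme than the observed one. The attainable
    minimum at 999 permutations is therefore 0.001.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    z_x = standardize(x)
    z_y = standardize(y)
    I_obs = bivariate_moran(z_x, z_y, W)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(z_y, (n_perm, 1)), axis=1)  # (n_perm, n)
    # lag of each permuted y: gather neighbor values then weight
    lagged = (W.weights[None, :, :] * perms[:, W.neighbors]).sum(axis=2)
    I_null = lagged @ z_x / W.n  # (n_perm,)
    if alternative == "greater":
        b = int(np.sum(I_null >= I_obs))
    elif alternative == "less":
        b = int(np.sum(I_null <= I_obs))
    else:
        b = int(np.sum(np.abs(I_null) >= abs(I_obs)))
    return MoranResult(
        I_obs=I_obs,
        n_perm=n_perm,
        p_value=(1 + b) / (n_perm + 1),
        alternative=alternative,
        null_mean=float(I_null.mean()),
        null_sd=float(I_null.std(ddof=0)),
        seed=seed,
    )


def bivariate_lisa(
    x: np.ndarray,
    y: np.ndarray,
    W: WeightMatrix,
    n_perm: int = 999,
    alpha: float = 0.05,
    adjust: str = "BH",
    seed: int = 0,
) -> pd.DataFrame:
    """Bivariate local indicators of spatial association.

    local_I_i = z_x,i * lag(z_y)_i; the quadrant comes from the signs of
    (z_x,i, lag(z_y)_i) with HH = both positive. Local p-values use
    conditional permutation: spot i's own z_x is held fixed while the k
    neighbor values are drawn from z_y excluding spot i; the one-sided p is
    taken in the direction of the observed local statistic and flagged
    significant after Benjamini-Hochberg adjustment across spots.
    """
    z_x = standardize(x)
    z_y = standardize(y)
    n = W.n
    if len(z_x) != n or len(z_y) != n:
        raise ValueError("length mismatch")
    lag_y = W.lag(z_y)
    local_I = z_x * lag_y
    quad = np.where(
        z_x > 0,
        np.where(lag_y > 0, "HH", "HL"),
        np.where(lag_y > 0, "LH", "LL"),
    )

    rng = np.random.default_rng(seed)
    k = W.k
    # one table of random draws of k indices from the n-1 "others", shared
    # across spots; per spot the indices are shifted around its own position
    perm_tab = rng.permuted(np.tile(np.arange(n - 1), (n_perm, 1)), axis=1)[:, :k]
    idx_adj = perm_tab[None, :, :] + (perm_tab[None, :, :] >= np.arange(n)[:, None, None])
    lag_perm = (W.weights[:, None, :] * z_y[idx_adj]).sum(axis=2)  # (n, n_perm)
    local_perm = z_x[:, None] * lag_perm

    null_mean = local_perm.mean(axis=1)
    direction_up = local_I >= null_mean
    b = np.where(
        direction_up,
        (local_perm >= local_I[:, None]).sum(axis=1),
        (local_perm <= local_I[:, None]).sum(axis=1),
    )
    p_local = (1 + b) / (n_perm + 1)

    if adjust == "BH":
        sig = multipletests(p_local, alpha=alpha, method="fdr_bh")[0]
    elif adjust == "none":
        sig = p_local < alpha
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    return pd.DataFrame(
        {
            "local_I": local_I,
            "quadrant": quad,
            "p_local": p_local,
            "significant": sig,
        }
    )


# ------------------------------------------------------------ rank tests

def _midranks(pooled: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(pooled, method="average")


def _tie_counts(pooled: np.ndarray) -> np.ndarray:
    _, counts = np.unique(pooled, return_counts=True)
    return counts


def _exact_u_sf(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U (count form) by dynamic programming.

    Returns an array c of length n1*n2 + 1 with c[u] = #{labelings with
    U = u}; total sums to C(n1+n2, n1). Valid only without ties.
    """
    max_u = n1 * n2
    # ways[j][u]: ways to place j sample-1 items among first i with U partial
    ways = np.zeros((n1 + 1, max_u + 1), dtype=float)
    ways[0, 0] = 1.0
    for i in range(1, n1 + n2 + 1):
        new = ways.copy()
        for j in range(min(i, n1), 0, -1):
            u = i - j  # items of sample 2 preceding this sample-1 item
            if u <= max_u:
                new[j, u:] += ways[j - 1, : max_u + 1 - u]
        ways = new
    return ways[n1]


def rank_sum_test(
    a: np.ndarray,
    b: np.ndarray,
    alternative: str = "two_sided",
    exact_limit: int = 10,
) -> RankTestResult:
    """Mann-Whitney / Wilcoxon rank-sum test.

    The statistic is U_a = #{pairs with a > b} (+1/2 per tie, via midranks).
    Exact p by full enumeration of labelings when max(n_a, n_b) <=
    ``exact_limit`` and there are no ties; otherwise a normal approximation
    with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    R1 = ranks[:n1].sum()
    U = R1 - n1 * (n1 + 1) / 2.0
    ties = _tie_counts(pooled)
    has_ties = bool(np.any(ties > 1))

    if max(n1, n2) <= exact_limit and not has_ties:
        counts = _exact_u_sf(n1, n2)
        total = counts.sum()
        u_int = int(round(U))
        p_ge = counts[u_int:].sum() / total
        p_le = counts[: u_int + 1].sum() / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return RankTestResult(float(U), float(p), alternative, "exact", False)

    mu = n1 * n2 / 2.0
    N = n1 + n2
    tie_term = (ties**3 - ties).sum() / (N * (N - 1)) if N > 1 else 0.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        # every observation identical: no evidence either way
        return RankTestResult(float(U), 1.0, alternative, "normal_approx", has_ties)
    sd = np.sqrt(var)
    if alternative == "greater":
        p = float(norm.sf((U - mu - 0.5) / sd))
    elif alternative == "less":
        p = float(norm.cdf((U - mu + 0.5) / sd))
    else:
        z = (abs(U - mu) - 0.5) / sd
        p = float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))
    return RankTestResult(float(U), p, alternative, "normal_approx", has_ties)


def signed_rank_test(
    diffs: np.ndarray,
    alternative: str = "two_sided",
    exact_limit: int = 12,
) -> RankTestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped. Statistic W+ = sum of ranks (midranks for
    tied magnitudes) of positive differences. Exact p enumerates all 2^m
    sign patterns for m <= ``exact_limit``; otherwise normal approximation
    (mean sum(r)/2, variance sum(r^2)/4 — the midrank form, which absorbs
    ties) with continuity correction.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    m = len(d)
    if m == 0:
        raise ValueError("all differences are zero")
    if m < 3:
        raise ValueError("need >= 3 nonzero differences")
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    ranks = _midranks(np.abs(d))
    W = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < m

    if m <= exact_limit:
        patterns = (np.arange(2**m)[:, None] >> np.arange(m)) & 1  # (2^m, m)
        w_null = patterns @ ranks
        p_ge = float(np.mean(w_null >= W - 1e-12))
        p_le = float(np.mean(w_null <= W + 1e-12))
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return RankTestResult(W, p, alternative, "exact", has_ties)

    mu = ranks.sum() / 2.0
    sd = np.sqrt((ranks**2).sum() / 4.0)
    if alternative == "greater":
        p = float(norm.sf((W - mu - 0.5) / sd))
    elif alternative == "less":
        p = float(norm.cdf((W - mu + 0.5) / sd))
    else:
        z = (abs(W - mu) - 0.5) / sd
        p = float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))
    return RankTestResult(W, p, alternative, "normal_approx", has_ties)


# ----------------------------------------------- composite spatial tests

def distance_proximity_test(
    labels: StratumLabels,
    niche_mask: np.ndarray,
    lattice: SpotLattice,
    high_label: str = "high",
    low_label: str = "low",
) -> dict:
    """Are high-score spots closer to the exhausted niche than low-score spots?

    Computes each spot's minimum Euclidean distance to the niche set and
    compares the high vs low strata with a one-sided rank-sum test
    (alternative: high closer, i.e. smaller distances).
    """
    niche_mask = np.asarray(niche_mask, dtype=bool)
    d = min_distance_to_set(lattice, niche_mask)
    hi = d[labels.mask(high_label)]
    lo = d[labels.mask(low_label)]
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("empty stratum")
    test = rank_sum_test(hi, lo, alternative="less")
    return {
        "test": test,
        "median_high": float(np.median(hi)),
        "median_low": float(np.median(lo)),
        "n_high": len(hi),
        "n_low": len(lo),
        "n_niche": int(niche_mask.sum()),
    }


def tec_nec_comparison(
    expr_by_patient: dict,
    labels_by_patient: dict,
    genes: tuple[str, ...] = ("CD274", "TGFB1", "IL10", "IDO1"),
    alternative: str = "greater",
) -> pd.DataFrame:
    """Intra-patient TEC-vs-NEC contrast of immunosuppressive mediators.

    For each patient and gene, the mean expression over TEC and NEC spots is
    computed; per gene, a Wilcoxon signed-rank test is run over the
    patient-level paired differences (TEC minus NEC; default alternative:
    TEC higher).
    """
    patients = sorted(expr_by_patient)
    if sorted(labels_by_patient) != patients:
        raise ValueError("expression and labels patient sets differ")
    if len(patients) < 3:
        raise ValueError("need >= 3 patients for the paired test")
    rows = []
    per_patient = {g: [] for g in genes}
    for pid in patients:
        expr = expr_by_patient[pid]
        lab = labels_by_patient[pid]
        tec = lab.mask("TEC")
        nec = lab.mask("NEC")
        if tec.sum() < 3 or nec.sum() < 3:
            raise ValueError(f"patient {pid}: < 3 spots in a stratum")
        for g in genes:
            v = expr.gene(g)
            per_patient[g].append((float(v[tec].mean()), float(v[nec].mean())))
    for g in genes:
        pairs = np.array(per_patient[g])
        diffs = pairs[:, 0] - pairs[:, 1]
        test = signed_rank_test(diffs, alternative=alternative)
        rows.append(
            {
                "gene": g,
                "mean_tec": float(pairs[:, 0].mean()),
                "mean_nec": float(pairs[:, 1].mean()),
                "statistic": test.statistic,
                "p_value": test.p_value,
                "method": test.method,
                "n_patients": len(patients),
            }
        )
    return pd.DataFrame(rows)
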