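"""Normalization, deconvolution-weighted scoring, and spot stratification.

The central quantity is the *pure malignant score*: a gene's per-spot
expression multiplied by the deconvolved malignant cell fraction, which
strips stromal signal from a multi-cellular spot. Signature scores are
per-spot panel means; stratifications (high/low, TEC/NEC) are rank-based
quantile rules with recorded thresholds.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import (
    ExpressionMatrix,
    FractionTable,
    GeneSet,
    ScoreVector,
    StratumLabels,
)

log = logging.getLogger(__name__)


def normalize(expr: ExpressionMatrix, method: str = "cp10k_log1p") -> ExpressionMatrix:
    """Depth-normalize raw counts.

    ``cp10k_log1p`` scales each spot to 10,000 total counts then applies
    log(1 + x); zero-depth spots are dropped with a warning. ``none`` passes
    raw values through (relabelled normalized) for analyses that want the
    raw scale.
    """
    if expr.state != "raw_counts":
        raise ValueError("normalize expects raw counts")
    if method == "none":
        return ExpressionMatrix(
            list(expr.gene_ids),
            list(expr.spot_ids),
            expr.values.copy(),
            state="normalized",
            normalization={"method": "none"},
        )
    if method != "cp10k_log1p":
        raise ValueError(f"unknown normalization method {method!r}")
    depth = expr.values.sum(axis=0)
    if np.all(depth == 0):
        raise ValueError("all-zero expression matrix")
    keep = depth > 0
    if not keep.all():
        log.warning("dropping %d zero-depth spots", int((~keep).sum()))
    vals = expr.values[:, keep] / depth[keep][None, :] * 1e4
    vals = np.log1p(vals)
    return ExpressionMatrix(
        list(expr.gene_ids),
        [s for s, k in zip(expr.spot_ids, keep) if k],
        vals,
        state="normalized",
        normalization={"method": "cp10k_log1p", "scale": 1e4},
    )


def pure_malignant_score(
    expr: ExpressionMatrix,
    fractions: FractionTable,
    gene: str = "SLC1A3",
    cell_type: str = "malignant",
) -> ScoreVector:
    """score_i = expression_i(gene) * fraction_i(cell_type).

    Weighting by the deconvolved malignant fraction removes stromal
    contamination from the spot-level signal.
    """
    if expr.spot_ids != fractions.spot_ids:
        raise ValueError("expression and fractions not aligned on spot ids")
    e = expr.gene(gene)
    f = fractions.fraction(cell_type)
    return ScoreVector(
        list(expr.spot_ids),
        e * f,
        score_name=f"pure_{cell_type}_{gene}",
        normalization=dict(expr.normalization),
    )


def signature_score(expr: ExpressionMatrix, gene_set: GeneSet) -> ScoreVector:
    """Per-spot mean expression over the panel genes present in the matrix."""
    present = [g for g in gene_set.genes if g in expr.gene_ids]
    absent = [g for g in gene_set.genes if g not in expr.gene_ids]
    if absent:
        log.warning("signature %s: %d absent genes: %s", gene_set.name, len(absent), absent)
    if not present:
        raise ValueError(f"no genes of set {gene_set.name!r} present in matrix")
    idx = [expr.gene_ids.index(g) for g in present]
    return ScoreVector(
        list(expr.spot_ids),
        expr.values[idx].mean(axis=0),
        score_name=gene_set.name,
        normalization=dict(expr.normalization),
    )


def dichotomize(
    score: ScoreVector,
    rule: str = "median",
    labels: tuple[str, str] = ("high", "low"),
    q: float = 0.3,
) -> StratumLabels:
    """Split spots into high/low strata.

    ``median``: high = score > median, low = score <= median (ties low).
    ``quantile``: top ``q`` high, bottom ``q`` low, middle ``excluded``;
    quantiles use linear interpolation and ties go to the lower stratum.
    """
    v = score.values
    hi, lo = labels
    if rule == "median":
        if np.ptp(v) == 0:
            raise ValueError("constant score cannot be median-dichotomized")
        thr = float(np.median(v))
        out = np.where(v > thr, hi, lo).astype(object)
        thresholds = {"rule": "median", "threshold": thr}
    elif rule == "quantile":
        if not 0 < q < 0.5:
            raise ValueError("q must lie in (0, 0.5)")
        lo_thr = float(np.quantile(v, q))
        hi_thr = float(np.quantile(v, 1 - q))
        out = np.full(len(v), "excluded", dtype=object)
        out[v >= hi_thr] = hi
        out[v <= lo_thr] = lo
        thresholds = {"rule": "quantile", "q": q, "low": lo_thr, "high": hi_thr}
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return StratumLabels(list(score.spot_ids), out, thresholds)


def stratify_tec_nec(
    fractions: FractionTable,
    endothelial_q: float = 0.50,
    malignant_q: float = 0.30,
    endothelial_type: str = "endothelial",
    malignant_type: str = "malignant",
) -> StratumLabels:
    """TEC/NEC stratification of vascular-enriched spots.

    Vascular-enriched = endothelial fraction >= its median across all spots
    (top 50%). Within that subset, TEC = malignant fraction >= the subset's
    (1 - malignant_q) quantile (top 30% by default), NEC = <= the
    malignant_q quantile (bottom 30%), remainder ``other``; spots outside the
    vascular subset are ``excluded``.
    """
    endo = fractions.fraction(endothelial_type)
    mal = fractions.fraction(malignant_type)
    endo_thr = float(np.quantile(endo, 1 - endothelial_q))
    vascular = endo >= endo_thr
    n_vasc = int(vascular.sum())
    if n_vasc < 10:
        log.warning("only %d vascular-enriched spots; proceeding", n_vasc)
    sub = mal[vascular]
    hi_thr = float(np.quantile(sub, 1 - malignant_q))
    lo_thr = float(np.quantile(sub, malignant_q))
    out = np.full(len(endo), "excluded", dtype=object)
    out[vascular] = "other"
    out[vascular & (mal >= hi_thr)] = "TEC"
    out[vascular & (mal <= lo_thr)] = "NEC"
    return StratumLabels(
        list(fractions.spot_ids),
        out,
        {
            "endothelial_q": endothelial_q,
            "malignant_q": malignant_q,
            "endothelial_threshold": endo_thr,
            "malignant_high": hi_thr,
            "malignant_low": lo_thr,
        },
    )


def exhausted_niche_mask(
    exhaustion: ScoreVector, cd8a: np.ndarray
) -> np.ndarray:
    """Exhausted-T-cell niche spots: exhaustion score AND CD8A above medians."""
    cd8a = np.asarray(cd8a, dtype=float)
    if cd8a.shape[0] != len(exhaustion.spot_ids):
        raise ValueError("CD8A vector not aligned to exhaustion score")
    return (exhaustion.values > np.median(exhaustion.values)) & (
        cd8a > np.median(cd8a)
    )
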