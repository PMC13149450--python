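"""End-to-end orchestration of the spatial co-aggregation analysis.

``run_spatial`` chains: normalization -> deconvolution-weighted malignant
score + exhaustion signature -> k-nearest-neighbor weights -> global
bivariate Moran's I with Monte-Carlo permutations -> bivariate LISA ->
high/low proximity test against the exhausted niche -> annular-zone
exhaustion gradient with a LOESS core-to-margin trajectory -> TEC/NEC
stratification. One seed governs every stochastic stage; identical config
plus seed reproduces identical artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import graph, io, scoring, stats
from .datatypes import ExpressionMatrix, FractionTable, GeneSet, SpotLattice
from .synth import DEFAULT_EXHAUSTION_PANEL

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All analysis knobs. Defaults mirror the published analysis: k=6
    neighbors, 999 Monte-Carlo permutations, top-50% endothelial /
    top-vs-bottom-30% malignant TEC-NEC strata."""

    k: int = 6
    n_perm: int = 999
    alpha: float = 0.05
    alternative: str = "greater"
    normalization: str = "cp10k_log1p"
    malignant_gene: str = "SLC1A3"
    tcell_gene: str = "CD8A"
    exhaustion_panel: tuple[str, ...] = DEFAULT_EXHAUSTION_PANEL
    endothelial_q: float = 0.50
    malignant_q: float = 0.30
    deg_p_max: float = 0.05
    deg_abs_logfc_min: float = 1.2
    core_fraction_min: float = 0.5
    core_score_quantile: float = 0.70
    zone_width: float | None = None  # default 2 * lattice spacing estimate
    loess_span: float = 0.75
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exhaustion_panel"] = list(self.exhaustion_panel)
        return d


def _estimate_spacing(lattice: SpotLattice) -> float:
    """Median nearest-neighbor distance — the lattice pitch."""
    from scipy.spatial import cKDTree

    d, _ = cKDTree(lattice.coords).query(lattice.coords, k=2)
    return float(np.median(d[:, 1]))


def malignant_core_mask(
    score_values: np.ndarray,
    malignant_fraction: np.ndarray,
    fraction_min: float = 0.5,
    score_quantile: float = 0.70,
) -> np.ndarray:
    """Spots forming the malignant core: malignant fraction >= fraction_min
    AND pure malignant score >= its score_quantile across spots."""
    thr = np.quantile(score_values, score_quantile)
    mask = (malignant_fraction >= fraction_min) & (score_values >= thr)
    if not mask.any():
        raise ValueError("no spots qualify as malignant core; lower the thresholds")
    return mask


def run_spatial(
    lattice: SpotLattice,
    expr: ExpressionMatrix,
    fractions: FractionTable,
    config: RunConfig | None = None,
) -> dict:
    """Run the full single-section spatial analysis; returns a result bundle."""
    cfg = config or RunConfig()
    if expr.spot_ids != lattice.spot_ids or fractions.spot_ids != lattice.spot_ids:
        raise ValueError("expression / fractions / lattice not aligned on spot ids")

    norm = scoring.normalize(expr, method=cfg.normalization)
    if norm.spot_ids != lattice.spot_ids:  # zero-depth spots dropped
        keep = [lattice.spot_ids.index(s) for s in norm.spot_ids]
        lattice = SpotLattice(list(norm.spot_ids), lattice.coords[keep])
        fractions = FractionTable(
            list(norm.spot_ids), list(fractions.cell_types), fractions.values[keep]
        )

    mal_score = scoring.pure_malignant_score(
        norm, fractions, gene=cfg.malignant_gene, cell_type="malignant"
    )
    ex_score = scoring.signature_score(
        norm, GeneSet("exhaustion", list(cfg.exhaustion_panel))
    )
    cd8a = norm.gene(cfg.tcell_gene)

    W = graph.knn_weights(lattice, k=cfg.k, row_standardize=True)
    moran = stats.moran_mc_test(
        mal_score.values, ex_score.values, W,
        n_perm=cfg.n_perm, alternative=cfg.alternative, seed=cfg.seed,
    )
    lisa = stats.bivariate_lisa(
        mal_score.values, ex_score.values, W,
        n_perm=cfg.n_perm, alpha=cfg.alpha, seed=cfg.seed,
    )
    lisa.insert(0, "spot_id", lattice.spot_ids)

    niche = scoring.exhausted_niche_mask(ex_score, cd8a)
    labels = scoring.dichotomize(mal_score, rule="median")
    proximity = stats.distance_proximity_test(labels, niche, lattice)

    spacing = _estimate_spacing(lattice)
    zone_width = cfg.zone_width if cfg.zone_width is not None else 2.0 * spacing
    core = malignant_core_mask(
        mal_score.values, fractions.fraction("malignant"),
        cfg.core_fraction_min, cfg.core_score_quantile,
    )
    dists = graph.min_distance_to_set(lattice, core)
    zones = graph.annular_zones(dists, zone_width)
    zone_profile = (
        pd.DataFrame(
            {
                "zone": zones.zone,
                "exhaustion": ex_score.values,
                "malignant_score": mal_score.values,
            }
        )
        .groupby("zone")
        .agg(n_spots=("exhaustion", "size"),
             mean_exhaustion=("exhaustion", "mean"),
             mean_malignant_score=("malignant_score", "mean"))
        .reset_index()
    )
    profile = graph.core_margin_profile(
        lattice, core, ex_score.values, span=cfg.loess_span
    )

    tecnec = scoring.stratify_tec_nec(
        fractions, endothelial_q=cfg.endothelial_q, malignant_q=cfg.malignant_q
    )

    spots = pd.DataFrame(
        {
            "spot_id": lattice.spot_ids,
            "x": lattice.coords[:, 0],
            "y": lattice.coords[:, 1],
            "malignant_score": mal_score.values,
            "exhaustion_score": ex_score.values,
            "malignant_stratum": labels.labels,
            "exhausted_niche": niche,
            "core": core,
            "distance_to_core": dists,
            "zone": zones.zone,
            "tec_nec": tecnec.labels,
        }
    )

    return {
        "global": {
            "moran_I": moran.I_obs,
            "moran_p": moran.p_value,
            "moran_n_perm": moran.n_perm,
            "moran_alternative": moran.alternative,
            "moran_null_mean": moran.null_mean,
            "moran_null_sd": moran.null_sd,
            "proximity_p": proximity["test"].p_value,
            "proximity_statistic": proximity["test"].statistic,
            "proximity_median_high": proximity["median_high"],
            "proximity_median_low": proximity["median_low"],
            "n_spots": lattice.n_spots,
            "n_core": int(core.sum()),
            "n_niche": int(niche.sum()),
            "zone_width": zone_width,
        },
        "lisa": lisa,
        "zone_profile": zone_profile,
        "loess_profile": profile,
        "spots": spots,
        "moran": moran,
        "proximity": proximity,
        "tec_nec_labels": tecnec,
        "metadata": {"config": cfg.to_dict(), "seed": cfg.seed},
    }


def run_report(bundle: dict) -> str:
    """Human-readable markdown summary of a result bundle."""
    missing = [k for k in ("global", "lisa", "zone_profile") if k not in bundle]
    if missing:
        raise ValueError(f"bundle missing components: {missing}")
    g = bundle["global"]
    lisa = bundle["lisa"]
    sig = lisa[lisa["significant"]]
    quad_counts = sig["quadrant"].value_counts().to_dict()
    lines = [
        "# Spatial co-aggregation report",
        "",
        f"- Spots analyzed: {g['n_spots']}",
        f"- Global bivariate Moran's I: {g['moran_I']:.4f} "
        f"(one-sided MC p = {g['moran_p']:.4g}, {g['moran_n_perm']} permutations)",
        f"- Proximity test (high vs low malignant score, distance to exhausted "
        f"niche): p = {g['proximity_p']:.4g} "
        f"(median distance high = {g['proximity_median_high']:.3g}, "
        f"low = {g['proximity_median_low']:.3g})",
        f"- Malignant core: {g['n_core']} spots; exhausted niche: {g['n_niche']} spots",
        "",
        f"## LISA ({len(sig)} significant spots)"
        if len(sig)
        else "## LISA (0 significant spots)",
    ]
    for q in ("HH", "HL", "LH", "LL"):
        if q in quad_counts:
            lines.append(f"- {q}: {quad_counts[q]}")
    lines.append("")
    lines.append("## Exhaustion by annular zone")
    lines.append(bundle["zone_profile"].to_string(index=False))
    if "tec_nec" in bundle:
        lines.append("")
        lines.append("## TEC vs NEC immunosuppressive mediators")
        lines.append(bundle["tec_nec"].to_string(index=False))
    lines.append("")
    return "\n".join(lines)


def write_bundle(bundle: dict, out_dir) -> dict:
    """Serialize the bundle via the io layer."""
    return io.write_results(bundle, out_dir)
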