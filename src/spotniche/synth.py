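"""Synthetic Visium-like data with known ground truth.

The generator emulates the statistical structure of a glioblastoma section
profiled on a spot array: a roughly circular malignant core (sigmoid decay
of malignant fraction with distance from the core center), smooth
endothelial and T-cell fields, and negative-binomial counts in which

* ``SLC1A3`` tracks the malignant field,
* a T-cell exhaustion panel tracks an exhaustion field whose cross-spot
  correlation with the (smoothed) malignant field is set by a single knob
  ``coupling_gamma`` in [0, 1] — a convex mixture of the smoothed malignant
  field and an independent smooth field,
* the immunosuppressive mediators (CD274, TGFB1, IL10, IDO1) are uplifted
  where endothelium and malignancy co-occur (the TEC phenotype).

Everything downstream (deconvolution-weighted scores, bivariate Moran's I,
LISA, distance gradients, TEC/NEC contrasts) is therefore testable against
a known truth without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .datatypes import ExpressionMatrix, FractionTable, SpotLattice, SurvivalTable

#: Default T-cell exhaustion panel. The panel is a configurable stand-in:
#: these six markers are the canonical exhaustion TFs/checkpoints, but any
#: panel can be supplied through SimulationConfig.exhaustion_panel.
DEFAULT_EXHAUSTION_PANEL = ("PDCD1", "HAVCR2", "LAG3", "CTLA4", "TIGIT", "TOX")

#: Immunosuppressive mediators upregulated in tumor-associated endothelium.
IMMUNOSUPPRESSIVE_GENES = ("CD274", "TGFB1", "IL10", "IDO1")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic dataset. Same seed => bit-identical data."""

    n_rows: int = 20
    n_cols: int = 20
    grid: str = "hex"  # "hex" | "square"
    spacing: float = 1.0
    core_center: tuple[float, float] | None = None  # default: lattice centroid
    core_radius: float = 6.0
    core_sharpness: float = 1.0  # sigmoid temperature
    coupling_gamma: float = 0.9  # exhaustion-vs-malignant cross-correlation
    effect_beta_mal: float = 5.0  # SLC1A3 uplift per unit malignant fraction
    effect_beta_ex: float = 5.0  # exhaustion-panel uplift per unit field
    effect_beta_immunosup: float = 5.0  # mediator uplift in TEC-like spots
    library_size_mean: float = 5000.0
    nb_dispersion: float = 2.0  # negative-binomial size; var = mu + mu^2/r
    n_noise_genes: int = 50
    smooth_bandwidth: float | None = None  # default 2 * spacing
    exhaustion_panel: tuple[str, ...] = DEFAULT_EXHAUSTION_PANEL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.core_radius <= 0:
            raise ValueError("core_radius must be positive")
        if self.core_sharpness <= 0:
            raise ValueError("core_sharpness must be positive")
        if not 0.0 <= self.coupling_gamma <= 1.0:
            raise ValueError("coupling_gamma must lie in [0, 1]")
        for name in ("effect_beta_mal", "effect_beta_ex", "effect_beta_immunosup"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.grid not in ("hex", "square"):
            raise ValueError(f"unknown grid {self.grid!r}")

    @property
    def bandwidth(self) -> float:
        return 2.0 * self.spacing if self.smooth_bandwidth is None else self.smooth_bandwidth

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exhaustion_panel"] = list(self.exhaustion_panel)
        if d["core_center"] is not None:
            d["core_center"] = list(d["core_center"])
        return d


@dataclass
class GroundTruth:
    """Latent per-spot fields the generator drew from."""

    malignant_field: np.ndarray  # in [0, 1]
    endothelial_field: np.ndarray  # in [0, 1]
    tcell_field: np.ndarray  # in [0, 1]
    exhaustion_field: np.ndarray  # in [0, 1]
    core_mask: np.ndarray  # bool; malignant_field >= core_threshold
    core_threshold: float
    config: SimulationConfig


def generate_lattice(
    n_rows: int, n_cols: int, grid: str = "hex", spacing: float = 1.0
) -> SpotLattice:
    """Build a spot lattice in row-major order.

    Hex rows are offset by spacing/2 with row pitch spacing*sqrt(3)/2, so an
    interior spot has six equidistant neighbors — Visium geometry. Square
    rows are unoffset.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if grid not in ("hex", "square"):
        raise ValueError(f"unknown grid {grid!r}")
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    rows = rows.ravel()
    cols = cols.ravel()
    if grid == "hex":
        x = cols * spacing + (rows % 2) * (spacing / 2.0)
        y = rows * spacing * np.sqrt(3.0) / 2.0
    else:
        x = cols * spacing
        y = rows * spacing
    ids = [f"spot_{r}_{c}" for r, c in zip(rows, cols)]
    return SpotLattice(ids, np.column_stack([x, y]))


def _smooth_field(
    coords: np.ndarray, noise: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Gaussian-kernel smooth of white noise over spot coordinates, min-max
    rescaled to [0, 1] (constant fields map to 0.5)."""
    d2 = cdist(coords, coords, "sqeuclidean")
    K = np.exp(-d2 / (2.0 * bandwidth**2))
    f = K @ noise / K.sum(axis=1)
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.full_like(f, 0.5)
    return (f - lo) / (hi - lo)


def generate_fractions(
    lattice: SpotLattice, config: SimulationConfig
) -> tuple[FractionTable, GroundTruth]:
    """Draw per-spot cell-type fractions and the latent ground-truth fields.

    The malignant fraction is ``0.95 * logistic((R - d) / s)`` of the distance
    ``d`` to the core center (radius ``R``, sharpness ``s``): ~0.95 deep in
    the core, ~0 far outside. The remainder ``1 - malignant`` is split among
    endothelial / T-cell / other proportionally to smooth random fields, so
    rows sit exactly on the simplex and the malignant fraction decays
    monotonically from the core center.
    """
    rng = np.random.default_rng(config.seed)
    coords = lattice.coords
    center = (
        coords.mean(axis=0)
        if config.core_center is None
        else np.asarray(config.core_center, dtype=float)
    )
    d = np.linalg.norm(coords - center, axis=1)
    malignant = 0.95 / (1.0 + np.exp(-(config.core_radius - d) / config.core_sharpness))

    bw = config.bandwidth
    endo = _smooth_field(coords, rng.standard_normal(len(d)), bw)
    tcell = _smooth_field(coords, rng.standard_normal(len(d)), bw)
    other = _smooth_field(coords, rng.standard_normal(len(d)), bw)

    # Exhaustion: convex mixture of the smoothed malignant field and an
    # independent smooth field — coupling_gamma is the single truth knob.
    smoothed_mal = _smooth_field(coords, malignant, bw)
    indep = _smooth_field(coords, rng.standard_normal(len(d)), bw)
    exhaustion = config.coupling_gamma * smoothed_mal + (1 - config.coupling_gamma) * indep

    rest = np.column_stack([endo, tcell, other]) + 1e-6  # avoid 0/0
    rest = rest / rest.sum(axis=1, keepdims=True) * (1.0 - malignant)[:, None]
    values = np.column_stack([malignant, rest])

    fractions = FractionTable(
        list(lattice.spot_ids), ["malignant", "endothelial", "tcell", "other"], values
    )
    core_threshold = 0.5
    truth = GroundTruth(
        malignant_field=malignant,
        endothelial_field=endo,
        tcell_field=tcell,
        exhaustion_field=exhaustion,
        core_mask=malignant >= core_threshold,
        core_threshold=core_threshold,
        config=config,
    )
    return fractions, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, r: float) -> np.ndarray:
    """Negative-binomial counts with mean mu and size r (var = mu + mu^2/r)."""
    mu = np.maximum(mu, 1e-12)
    return rng.negative_binomial(r, r / (r + mu))


def generate_expression(
    lattice: SpotLattice,
    fractions: FractionTable,
    truth: GroundTruth,
    config: SimulationConfig,
) -> ExpressionMatrix:
    """Draw the genes x spots count matrix.

    Per-gene relative rates are ``base + beta * field``; per-spot library-size
    factors are lognormal; counts are negative-binomial with the configured
    dispersion. Gene panel: SLC1A3, CD8A, the exhaustion panel, the four
    immunosuppressive mediators, plus ``n_noise_genes`` unstructured genes.
    """
    if fractions.spot_ids != lattice.spot_ids:
        raise ValueError("fractions not aligned to lattice")
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = lattice.n_spots
    base = 0.5

    mal = truth.malignant_field
    ex = truth.exhaustion_field
    endo = truth.endothelial_field

    gene_ids: list[str] = []
    rates: list[np.ndarray] = []

    gene_ids.append("SLC1A3")
    rates.append(base + config.effect_beta_mal * mal)
    gene_ids.append("CD8A")
    rates.append(base + config.effect_beta_ex * ex)
    for g in config.exhaustion_panel:
        gene_ids.append(g)
        rates.append(base + config.effect_beta_ex * ex)
    for g in IMMUNOSUPPRESSIVE_GENES:
        gene_ids.append(g)
        rates.append(base + config.effect_beta_immunosup * endo * mal)
    noise_base = rng.lognormal(mean=np.log(base), sigma=0.4, size=config.n_noise_genes)
    for j in range(config.n_noise_genes):
        gene_ids.append(f"NOISE{j:04d}")
        rates.append(np.full(n, noise_base[j]))

    R = np.vstack(rates)  # (genes, spots)
    sf = rng.lognormal(mean=0.0, sigma=0.3, size=n)
    sf *= config.library_size_mean / (R.mean(axis=1).sum() * sf.mean())
    mu = R * sf[None, :]
    counts = _nb_draw(rng, mu, config.nb_dispersion).astype(float)
    return ExpressionMatrix(gene_ids, list(lattice.spot_ids), counts, state="raw_counts")


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[SpotLattice, FractionTable, GroundTruth, ExpressionMatrix]:
    """Convenience: lattice + fractions + truth + counts in one call."""
    lattice = generate_lattice(config.n_rows, config.n_cols, config.grid, config.spacing)
    fractions, truth = generate_fractions(lattice, config)
    expr = generate_expression(lattice, fractions, truth, config)
    return lattice, fractions, truth, expr


def generate_survival(
    n_patients: int,
    adverse_genes: Sequence[str],
    effect: float,
    seed: int,
    n_null_genes: int = 5,
    baseline_log_hazard: float = float(np.log(0.1)),
    censor_rate: float = 0.03,
) -> tuple[SurvivalTable, "pd.DataFrame", list[str]]:
    """Exponential survival fixture with planted adverse genes.

    Each patient's log-hazard is ``alpha + effect * 1[expr > median]``
    averaged over the adverse genes; censoring is independent exponential.
    ``effect > 0`` makes high expression adverse, ``effect < 0`` protective.
    Returns the survival table, a genes x patients expression frame, and the
    ground-truth adverse gene list.
    """
    import pandas as pd

    if n_patients < 4:
        raise ValueError("n_patients must be >= 4")
    rng = np.random.default_rng(seed)
    ids = [f"P{i:04d}" for i in range(n_patients)]
    genes = list(adverse_genes) + [f"NULL{j:03d}" for j in range(n_null_genes)]
    expr = pd.DataFrame(
        rng.lognormal(mean=2.0, sigma=0.7, size=(len(genes), n_patients)),
        index=genes,
        columns=ids,
    )
    if adverse_genes:
        above = (
            expr.loc[list(adverse_genes)].gt(
                expr.loc[list(adverse_genes)].median(axis=1), axis=0
            )
        ).mean(axis=0)
        log_hazard = baseline_log_hazard + effect * above.to_numpy()
    else:
        log_hazard = np.full(n_patients, baseline_log_hazard)
    t_event = rng.exponential(1.0 / np.exp(log_hazard))
    t_censor = rng.exponential(1.0 / censor_rate, size=n_patients)
    time = np.minimum(t_event, t_censor)
    event = t_event <= t_censor
    time = np.maximum(time, 1e-9)
    return SurvivalTable(ids, time, event), expr, list(adverse_genes)
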