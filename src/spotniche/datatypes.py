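"""Core data containers shared across the package.

Each container validates its invariants on construction so that malformed
inputs fail loudly at the boundary rather than deep inside a statistic.
All containers are plain dataclasses around numpy arrays / pandas frames;
spot order is the single source of alignment between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file or table violates its format contract."""


@dataclass
class SpotLattice:
    """Spot identifiers plus 2-D coordinates (same order)."""

    spot_ids: list[str]
    coords: np.ndarray  # (n, 2) float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if len(self.spot_ids) != self.coords.shape[0]:
            raise ValueError("spot_ids and coords length mismatch")
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise FormatError("duplicate spot ids")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("non-finite coordinates")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)


@dataclass
class ExpressionMatrix:
    """Genes x spots expression values with an explicit normalization state.

    ``state`` is ``"raw_counts"`` (integer-valued, straight from the
    sequencer / simulator) or ``"normalized"`` (any real-valued transform).
    """

    gene_ids: list[str]
    spot_ids: list[str]
    values: np.ndarray  # (genes, spots)
    state: str = "raw_counts"
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.spot_ids)} spots"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise FormatError("duplicate spot ids")
        if self.state not in ("raw_counts", "normalized"):
            raise ValueError(f"unknown state {self.state!r}")
        if np.any(self.values < 0) and self.state == "raw_counts":
            raise FormatError("negative entries in raw counts")
        if self.state == "raw_counts" and not np.allclose(
            self.values, np.round(self.values)
        ):
            raise FormatError("raw_counts must be integer-valued")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def gene(self, symbol: str) -> np.ndarray:
        """Return the per-spot vector for one gene symbol (exact match)."""
        try:
            i = self.gene_ids.index(symbol)
        except ValueError:
            raise KeyError(f"gene {symbol!r} not present") from None
        return self.values[i]


@dataclass
class FractionTable:
    """Per-spot cell-type proportions on the simplex (deconvolution surrogate)."""

    spot_ids: list[str]
    cell_types: list[str]
    values: np.ndarray  # (spots, types)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.spot_ids), len(self.cell_types)):
            raise ValueError("fractions shape inconsistent with ids")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise FormatError("fractions outside [0, 1]")
        sums = self.values.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise FormatError("fraction rows do not sum to 1 within 1e-6")

    def fraction(self, cell_type: str) -> np.ndarray:
        try:
            j = self.cell_types.index(cell_type)
        except ValueError:
            raise KeyError(f"cell type {cell_type!r} not present") from None
        return self.values[:, j]


@dataclass
class GeneSet:
    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        # preserve order, drop duplicates
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g, None)
        self.genes = list(seen)


@dataclass
class SurvivalTable:
    """Right-censored survival data: one row per sample."""

    sample_ids: list[str]
    time: np.ndarray  # positive
    event: np.ndarray  # bool, True = death observed

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        if not (len(self.sample_ids) == len(self.time) == len(self.event)):
            raise ValueError("survival columns length mismatch")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if np.any(self.time <= 0) or not np.all(np.isfinite(self.time)):
            raise FormatError("survival times must be positive and finite")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class WeightMatrix:
    """Sparse k-nearest-neighbor spatial weights.

    ``neighbors`` holds, per spot, the indices of its k neighbors (ascending
    distance, ties broken by ascending index); ``weights`` the matching
    weights. ``w_ii = 0`` always (no self-neighbors).
    """

    n: int
    neighbors: np.ndarray  # (n, k) int
    weights: np.ndarray  # (n, k) float
    row_standardized: bool

    def __post_init__(self) -> None:
        self.neighbors = np.asarray(self.neighbors, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.neighbors.shape != self.weights.shape:
            raise ValueError("neighbors/weights shape mismatch")
        if self.neighbors.shape[0] != self.n:
            raise ValueError("neighbor rows != n")
        if np.any(self.neighbors < 0) or np.any(self.neighbors >= self.n):
            raise ValueError("neighbor index out of range")
        rows = np.repeat(np.arange(self.n), self.neighbors.shape[1])
        if np.any(self.neighbors.ravel() == rows):
            raise ValueError("self-neighbor (w_ii != 0)")
        if self.row_standardized:
            sums = self.weights.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-12):
                raise ValueError("row-standardized rows must sum to 1")

    @property
    def k(self) -> int:
        return self.neighbors.shape[1]

    def to_dense(self) -> np.ndarray:
        W = np.zeros((self.n, self.n))
        for i in range(self.n):
            W[i, self.neighbors[i]] = self.weights[i]
        return W

    def lag(self, z: np.ndarray) -> np.ndarray:
        """Spatial lag: lag_i = sum_j w_ij z_j."""
        z = np.asarray(z, dtype=float)
        if z.shape[0] != self.n:
            raise ValueError("length mismatch between z and weight matrix")
        return (self.weights * z[self.neighbors]).sum(axis=1)


@dataclass
class ZoneAssignment:
    """Concentric annular zones around the malignant core."""

    distances: np.ndarray
    zone: np.ndarray  # int >= 0
    zone_width: float


@dataclass
class ScoreVector:
    spot_ids: list[str]
    values: np.ndarray
    score_name: str
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.spot_ids) != len(self.values):
            raise ValueError("score length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite score values")


@dataclass
class StratumLabels:
    spot_ids: list[str]
    labels: np.ndarray  # array of str
    thresholds: dict

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.spot_ids) != len(self.labels):
            raise ValueError("label length mismatch")

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label


@dataclass
class MoranResult:
    I_obs: float
    n_perm: int
    p_value: float
    alternative: str
    null_mean: float
    null_sd: float
    seed: int


@dataclass
class RankTestResult:
    statistic: float
    p_value: float
    alternative: str
    method: str  # "exact" | "normal_approx"
    tie_correction: bool


@dataclass
class KMCurve:
    """Product-limit survival curve: S(t) right-continuous step function."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median: float  # nan if never reaches 0.5

    def evaluate(self, t: float) -> float:
        """S(t) for arbitrary t >= 0."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def as_series(score: ScoreVector) -> pd.Series:
    return pd.Series(score.values, index=score.spot_ids, name=score.score_name)
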