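import numpy as np
import pytest

import spotniche as sn


@pytest.fixture(scope="session")
def strong_dataset():
    """400-spot hex lattice with strong malignant-exhaustion coupling
    (gamma=0.9) — the canonical co-aggregation scenario."""
    cfg = sn.SimulationConfig(
        n_rows=20, n_cols=20, grid="hex", core_radius=6.0,
        coupling_gamma=0.9, seed=3,
    )
    lattice, fractions, truth, expr = sn.simulate_dataset(cfg)
    return cfg, lattice, fractions, truth, expr


@pytest.fixture(scope="session")
def strong_scores(strong_dataset):
    """Normalized scores + weights computed once from the strong dataset."""
    cfg, lattice, fractions, truth, expr = strong_dataset
    norm = sn.normalize(expr)
    mal = sn.pure_malignant_score(norm, fractions)
    ex = sn.signature_score(norm, sn.GeneSet("exhaustion", list(sn.DEFAULT_EXHAUSTION_PANEL)))
    W = sn.knn_weights(lattice, k=6)
    return {
        "lattice": lattice, "fractions": fractions, "truth": truth,
        "norm": norm, "mal": mal, "ex": ex, "W": W,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_lattice(rng: np.random.Generator, n: int) -> sn.SpotLattice:
    return sn.SpotLattice(
        [f"s{i}" for i in range(n)], rng.uniform(0, 10, size=(n, 2))
    )
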