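"""Moran / LISA and rank tests against hand evaluations, brute-force
double sums, full enumerations, and scipy as an independent oracle."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

import spotniche as sn
from .conftest import random_lattice


def moran_double_sum(z_x, z_y, W_dense):
    """Naive O(n^2) oracle for the bivariate statistic."""
    n = len(z_x)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += z_x[i] * W_dense[i, j] * z_y[j]
    return total / n


def mutual_pair():
    lat = sn.SpotLattice(["a", "b"], [[0, 0], [1, 0]])
    return sn.knn_weights(lat, k=1)


class TestStandardize:
    def test_population_closed_form(self):
        np.testing.assert_allclose(sn.standardize(np.array([0.0, 2.0])), [-1, 1])

    def test_sample_closed_form(self):
        np.testing.assert_allclose(
            sn.standardize(np.array([0.0, 2.0]), ddof=1),
            [-1 / np.sqrt(2), 1 / np.sqrt(2)],
        )

    def test_any_input_mean_zero_unit_sd(self, rng):
        z = sn.standardize(rng.random(50))
        assert abs(z.mean()) < 1e-12 and abs(z.std(ddof=0) - 1) < 1e-12

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            sn.standardize(np.full(5, 3.0))


class TestBivariateMoran:
    def test_antithetic_pair_gives_minus_one(self):
        W = mutual_pair()
        z = sn.standardize(np.array([0.0, 2.0]))
        assert sn.bivariate_moran(z, z.copy(), W) == pytest.approx(-1.0)

    def test_aligned_pair_gives_plus_one(self):
        W = mutual_pair()
        zx = sn.standardize(np.array([0.0, 2.0]))
        zy = sn.standardize(np.array([2.0, 0.0]))
        assert sn.bivariate_moran(zx, zy, W) == pytest.approx(1.0)

    def test_matches_double_sum_oracle(self, rng):
        lat = random_lattice(rng, 20)
        W = sn.knn_weights(lat, k=4)
        zx = sn.standardize(rng.random(20))
        zy = sn.standardize(rng.random(20))
        oracle = moran_double_sum(zx, zy, W.to_dense())
        assert sn.bivariate_moran(zx, zy, W) == pytest.approx(oracle, abs=1e-12)

    def test_unstandardized_input_rejected(self, rng):
        lat = random_lattice(rng, 10)
        W = sn.knn_weights(lat, k=3)
        with pytest.raises(ValueError, match="standardized"):
            sn.bivariate_moran(rng.random(10) + 5, sn.standardize(rng.random(10)), W)


class TestMoranMCTest:
    def test_same_seed_reproducible(self, rng):
        lat = random_lattice(rng, 40)
        W = sn.knn_weights(lat, k=6)
        x, y = rng.random(40), rng.random(40)
        a = sn.moran_mc_test(x, y, W, seed=9)
        b = sn.moran_mc_test(x, y, W, seed=9)
        assert a.p_value == b.p_value and a.null_mean == b.null_mean

    def test_perfect_coupling_attains_minimum_p(self, strong_scores):
        s = strong_scores
        res = sn.moran_mc_test(s["mal"].values, s["ex"].values, s["W"], seed=0)
        assert res.I_obs > 0
        assert res.p_value == pytest.approx(1 / 1000)

    def test_null_mean_near_zero_for_iid_inputs(self, rng):
        lat = random_lattice(rng, 60)
        W = sn.knn_weights(lat, k=6)
        res = sn.moran_mc_test(rng.random(60), rng.random(60), W, n_perm=999, seed=1)
        assert abs(res.null_mean) <= 4 * res.null_sd / np.sqrt(res.n_perm)

    def test_minimum_permutations_enforced(self, rng):
        lat = random_lattice(rng, 10)
        W = sn.knn_weights(lat, k=3)
        with pytest.raises(ValueError):
            sn.moran_mc_test(rng.random(10), rng.random(10), W, n_perm=10)


class TestBivariateLisa:
    def test_mean_local_equals_global(self, rng):
        lat = random_lattice(rng, 50)
        W = sn.knn_weights(lat, k=6)
        x, y = rng.random(50), rng.random(50)
        lisa = sn.bivariate_lisa(x, y, W, n_perm=99, seed=2)
        g = sn.bivariate_moran(sn.standardize(x), sn.standardize(y), W)
        assert lisa["local_I"].mean() == pytest.approx(g, abs=1e-9)

    def test_antithetic_pair_quadrants(self):
        W = mutual_pair()
        lisa = sn.bivariate_lisa(
            np.array([0.0, 2.0]), np.array([0.0, 2.0]), W, n_perm=19, seed=0
        )
        assert list(lisa["quadrant"]) == ["LH", "HL"]
        np.testing.assert_allclose(lisa["local_I"], [-1.0, -1.0])

    def test_strong_coupling_dominated_by_coherent_domains(self, strong_scores):
        # positive co-aggregation concentrates significance in the coherent
        # quadrants; within the malignant half of spots HH is the majority
        s = strong_scores
        lisa = sn.bivariate_lisa(s["mal"].values, s["ex"].values, s["W"], seed=0)
        sig = lisa[lisa["significant"]]
        assert len(sig) > 0
        assert sig["quadrant"].isin(["HH", "LL"]).mean() > 0.9
        zx = sn.standardize(s["mal"].values)
        sig_high = lisa[lisa["significant"] & (zx > 0)]
        assert (sig_high["quadrant"] == "HH").mean() > 0.5

    def test_reproducible_under_seed(self, rng):
        lat = random_lattice(rng, 30)
        W = sn.knn_weights(lat, k=5)
        x, y = rng.random(30), rng.random(30)
        a = sn.bivariate_lisa(x, y, W, n_perm=99, seed=5)
        b = sn.bivariate_lisa(x, y, W, n_perm=99, seed=5)
        assert a.equals(b)


class TestRankSum:
    def test_exact_small_example(self):
        res = sn.rank_sum_test(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_multisets_u_half_and_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        res = sn.rank_sum_test(a, a.copy())
        assert res.statistic == pytest.approx(len(a) ** 2 / 2)
        assert res.p_value == 1.0

    @pytest.mark.parametrize("alternative", ["greater", "less", "two_sided"])
    def test_exact_matches_scipy(self, rng, alternative):
        scipy_alt = {"greater": "greater", "less": "less", "two_sided": "two-sided"}
        for _ in range(10):
            a = rng.permutation(20)[:6].astype(float)
            b = np.setdiff1d(np.arange(20), a)[:7].astype(float)
            res = sn.rank_sum_test(a, b, alternative=alternative)
            ref = sps.mannwhitneyu(a, b, alternative=scipy_alt[alternative], method="exact")
            assert res.method == "exact"
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_close_to_exact_for_n8(self):
        # exhaustive: every attainable U for n_a = n_b = 8, no ties
        from spotniche.stats import _exact_u_sf

        n = 8
        counts = _exact_u_sf(n, n)
        total = counts.sum()
        assert total == pytest.approx(12870)  # C(16, 8)
        mu, sd = n * n / 2, np.sqrt(n * n * (2 * n + 1) / 12)
        for u in range(n * n + 1):
            exact = counts[u:].sum() / total
            approx = sps.norm.sf((u - mu - 0.5) / sd)
            assert abs(exact - approx) < 0.01

    def test_ties_fall_back_to_corrected_normal(self):
        a = np.array([1.0, 1.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 2.0, 4.0])
        res = sn.rank_sum_test(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.method == "normal_approx" and res.tie_correction
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            sn.rank_sum_test(np.array([]), np.array([1.0]))


class TestSignedRank:
    def test_three_positive_one_sided(self):
        res = sn.signed_rank_test(np.array([1.0, 2.0, 3.0]), alternative="greater")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 8)

    def test_symmetric_pairs_two_sided_p_one(self):
        res = sn.signed_rank_test(np.array([1.0, -1.0, 2.0, -2.0]))
        assert res.p_value == 1.0

    def test_exact_matches_scipy(self, rng):
        for _ in range(10):
            d = rng.standard_normal(9)
            d = d[np.abs(d) > 1e-6]
            if len(d) < 3 or len(np.unique(np.abs(d))) < len(d):
                continue
            res = sn.signed_rank_test(d, alternative="two_sided")
            ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_m12_exact_vs_normal_within_002(self, rng):
        for trial in range(5):
            d = rng.standard_normal(12)
            d = np.where(d == 0, 0.1, d)
            exact = sn.signed_rank_test(d, alternative="greater", exact_limit=12)
            approx = sn.signed_rank_test(d, alternative="greater", exact_limit=3)
            assert exact.method == "exact" and approx.method == "normal_approx"
            assert abs(exact.p_value - approx.p_value) < 0.02

    def test_zeros_dropped_and_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sn.signed_rank_test(np.zeros(5))


class TestDistanceProximity:
    def test_niche_equal_to_high_stratum_forces_order(self, rng):
        lat = random_lattice(rng, 60)
        score = sn.ScoreVector(lat.spot_ids, lat.coords[:, 0], "s")
        labels = sn.dichotomize(score)
        niche = labels.mask("high")
        out = sn.distance_proximity_test(labels, niche, lat)
        assert out["median_high"] == 0.0
        assert out["test"].p_value < 0.001

    def test_symmetric_construction_not_significant(self):
        # mirror-image lattice: high and low strata equidistant from niche
        xs = np.arange(1, 7, dtype=float)
        coords = np.column_stack([np.concatenate([-xs, xs]), np.zeros(12)])
        lat = sn.SpotLattice([f"s{i}" for i in range(12)], coords)
        labels = sn.StratumLabels(
            lat.spot_ids, np.array(["high"] * 6 + ["low"] * 6, dtype=object), {}
        )
        niche = np.zeros(12, dtype=bool)
        niche[[0, 6]] = True  # one niche spot on each side, same offsets
        out = sn.distance_proximity_test(labels, niche, lat)
        assert out["test"].p_value >= 0.5


class TestTecNecComparison:
    def _patient(self, seed, beta):
        cfg = sn.SimulationConfig(
            n_rows=12, n_cols=12, core_radius=3.6,
            effect_beta_immunosup=beta, seed=seed,
        )
        lat, frac, truth, expr = sn.simulate_dataset(cfg)
        return sn.normalize(expr), sn.stratify_tec_nec(frac)

    def test_identical_expression_hits_all_zero_error(self):
        # constant expression -> TEC mean == NEC mean in every patient ->
        # all paired differences zero -> degenerate-input error
        expr_by, lab_by = {}, {}
        for i in range(3):
            e, l = self._patient(800 + i, 5.0)
            expr_by[f"p{i}"] = sn.ExpressionMatrix(
                e.gene_ids, e.spot_ids, np.ones_like(e.values), state="normalized"
            )
            lab_by[f"p{i}"] = l
        with pytest.raises(ValueError):
            sn.tec_nec_comparison(expr_by, lab_by)

    def test_five_patients_strong_effect_all_mediators_significant(self):
        expr_by, lab_by = {}, {}
        for i in range(5):
            e, l = self._patient(700 + i, 5.0)
            expr_by[f"p{i}"] = e
            lab_by[f"p{i}"] = l
        df = sn.tec_nec_comparison(expr_by, lab_by)
        assert set(df["gene"]) == set(sn.IMMUNOSUPPRESSIVE_GENES)
        assert (df["p_value"] < 0.05).all()

    def test_four_patient_p_matches_enumeration_oracle(self):
        expr_by, lab_by = {}, {}
        for i in range(4):
            e, l = self._patient(900 + i, 5.0)
            expr_by[f"p{i}"] = e
            lab_by[f"p{i}"] = l
        df = sn.tec_nec_comparison(expr_by, lab_by)
        for _, row in df.iterrows():
            # recompute the paired diffs and enumerate the 2^4 sign patterns
            diffs = []
            for pid in sorted(expr_by):
                v = expr_by[pid].gene(row["gene"])
                tec, nec = lab_by[pid].mask("TEC"), lab_by[pid].mask("NEC")
                diffs.append(v[tec].mean() - v[nec].mean())
            diffs = np.array(diffs)
            ranks = sps.rankdata(np.abs(diffs))
            w_obs = ranks[diffs > 0].sum()
            count = 0
            for signs in range(16):
                bits = [(signs >> b) & 1 for b in range(4)]
                if (ranks * np.array(bits)).sum() >= w_obs - 1e-12:
                    count += 1
            assert row["p_value"] == pytest.approx(count / 16)
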