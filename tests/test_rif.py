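"""RIF metrics: formula oracles, z-scoring, bootstrap null, extreme calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rifnet.rif import (BootstrapNull, build_rif_input, call_extreme_trfs,
                        expressed_features, rif_bootstrap_null, rif_scores,
                        zscore_panel, RIFInput)
from rifnet.simulate import SimConfig, simulate_experiment

from conftest import make_matrix


def naive_rif(a, d, e1, e2, r1, r2):
    """Double-loop evaluation of the two printed formulas."""
    n_trf, n_de = r1.shape
    rif1 = np.zeros(n_trf)
    rif2 = np.zeros(n_trf)
    for i in range(n_trf):
        s1 = s2 = 0.0
        for j in range(n_de):
            s1 += a[j] * d[j] * (r1[i, j] - r2[i, j]) ** 2
            s2 += (e1[j] * r1[i, j]) ** 2 - (e2[j] * r2[i, j]) ** 2
        rif1[i] = s1 / n_de
        rif2[i] = s2 / n_de
    return rif1, rif2


def random_rif_input(rng, n_trf=50, n_de=30) -> RIFInput:
    e1 = rng.uniform(0, 8, size=n_de)
    e2 = rng.uniform(0, 8, size=n_de)
    r1 = rng.uniform(-1, 1, size=(n_trf, n_de))
    r2 = rng.uniform(-1, 1, size=(n_trf, n_de))
    ones = np.ones_like(r1, dtype=bool)
    return RIFInput(trf_ids=[f"t{i}" for i in range(n_trf)],
                    de_ids=[f"g{j}" for j in range(n_de)],
                    a=(e1 + e2) / 2, d=e1 - e2, e1=e1, e2=e2, r1=r1, r2=r2,
                    r1_defined=ones, r2_defined=ones)


class TestRifScores:
    def test_vectorized_equals_double_loop_oracle(self, rng):
        rin = random_rif_input(rng)
        out = rif_scores(rin)
        rif1, rif2 = naive_rif(rin.a, rin.d, rin.e1, rin.e2, rin.r1, rin.r2)
        assert np.abs(out["rif1"].to_numpy() - rif1).max() < 1e-10
        assert np.abs(out["rif2"].to_numpy() - rif2).max() < 1e-10

    def test_rif1_zero_when_coexpression_group_identical(self, rng):
        rin = random_rif_input(rng, n_trf=10, n_de=8)
        rin.r2 = rin.r1.copy()
        assert (rif_scores(rin)["rif1"] == 0.0).all()

    def test_rif2_zero_when_expression_and_correlation_match(self, rng):
        rin = random_rif_input(rng, n_trf=6, n_de=5)
        rin.r2 = rin.r1.copy()
        rin.e2 = rin.e1.copy()
        rin.d = rin.e1 - rin.e2
        rin.a = (rin.e1 + rin.e2) / 2
        out = rif_scores(rin)
        assert (out["rif1"] == 0.0).all()
        assert (out["rif2"] == 0.0).all()

    def test_two_by_two_hand_evaluation(self):
        # a=(2,3), d=(1,-1), e1=(2.5,2.5), e2=(1.5,3.5)
        e1 = np.array([2.5, 2.5])
        e2 = np.array([1.5, 3.5])
        r1 = np.array([[0.5, -0.5], [1.0, 0.0]])
        r2 = np.array([[0.0, 0.5], [-1.0, 0.0]])
        ones = np.ones_like(r1, dtype=bool)
        rin = RIFInput(["t0", "t1"], ["g0", "g1"], a=(e1 + e2) / 2,
                       d=e1 - e2, e1=e1, e2=e2, r1=r1, r2=r2,
                       r1_defined=ones, r2_defined=ones)
        out = rif_scores(rin)
        # hand sums: rif1_0 = (2*1*0.25 + 3*(-1)*1)/2 = -1.25
        #            rif1_1 = (2*1*4 + 0)/2 = 4
        assert out["rif1"].to_numpy() == pytest.approx([-1.25, 4.0],
                                                       abs=1e-12)
        # rif2_0 = ((2.5*0.5)^2-(1.5*0)^2 + (2.5*-0.5)^2-(3.5*0.5)^2)/2
        rif2_0 = (1.5625 - 0 + 1.5625 - 3.0625) / 2
        rif2_1 = ((2.5 ** 2 - 1.5 ** 2) + 0) / 2
        assert out["rif2"].to_numpy() == pytest.approx([rif2_0, rif2_1],
                                                       abs=1e-12)

    def test_label_swap_with_d_negation_leaves_rif1_invariant(self, rng):
        rin = random_rif_input(rng, n_trf=12, n_de=9)
        swapped = RIFInput(rin.trf_ids, rin.de_ids, a=rin.a, d=-rin.d,
                           e1=rin.e2, e2=rin.e1, r1=rin.r2, r2=rin.r1,
                           r1_defined=rin.r1_defined,
                           r2_defined=rin.r2_defined)
        out, out_sw = rif_scores(rin), rif_scores(swapped)
        assert np.allclose(out["rif1"], -out_sw["rif1"], atol=1e-12)
        assert np.allclose(out["rif2"], -out_sw["rif2"], atol=1e-12)


class TestBuildInput:
    def test_correlations_match_hand_computed_pearson(self):
        x = np.array([[1.0, 2.0, 3.0, 6.0, 5.0, 2.0, 1.0, 4.0],
                      [2.0, 1.0, 5.0, 4.0, 3.0, 3.0, 2.0, 8.0]])
        m = make_matrix(x, 4, 4, feature_ids=["gene", "trf"])
        rin = build_rif_input(m, ["gene"], ["trf"], min_fpkm=0.0)
        lg = np.log2(x + 1.0)
        for cols, r in ((slice(0, 4), rin.r1[0, 0]),
                        (slice(4, 8), rin.r2[0, 0])):
            a, b = lg[0, cols], lg[1, cols]
            expected = (((a - a.mean()) * (b - b.mean())).sum()
                        / np.sqrt(((a - a.mean()) ** 2).sum()
                                  * ((b - b.mean()) ** 2).sum()))
            assert r == pytest.approx(expected, abs=1e-12)

    def test_d_equals_e1_minus_e2_by_construction(self, small_matrix):
        rin = build_rif_input(small_matrix, ["F0", "F1"], ["F5", "F6"],
                              min_fpkm=0.0)
        assert np.allclose(rin.d, rin.e1 - rin.e2)
        assert np.allclose(rin.a, (rin.e1 + rin.e2) / 2)

    def test_constant_de_gene_gets_zero_flagged_correlations(self):
        x = np.vstack([np.full(8, 3.0),
                       np.arange(8, dtype=float) + 1.0])
        m = make_matrix(x, 4, 4, feature_ids=["flatgene", "trf"])
        rin = build_rif_input(m, ["flatgene"], ["trf"], min_fpkm=0.0)
        assert rin.r1[0, 0] == 0.0 and rin.r2[0, 0] == 0.0
        assert not rin.r1_defined[0, 0] and not rin.r2_defined[0, 0]
        assert np.isfinite(rin.a[0])
        assert (rif_scores(rin)["rif1"] == 0.0).all()

    def test_empty_de_set_errors(self, small_matrix):
        with pytest.raises(ValueError, match="non-empty"):
            build_rif_input(small_matrix, [], ["F1"])


class TestZscore:
    def test_one_two_three_maps_to_unit_steps(self):
        assert zscore_panel([1.0, 2.0, 3.0]) == pytest.approx([-1, 0, 1])

    def test_output_mean_zero_sd_one(self, rng):
        z = zscore_panel(rng.normal(5, 3, size=100))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(-50, 50), st.floats(0.01, 50))
    def test_affine_equivariance(self, b, a):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        z = zscore_panel(x)
        assert np.allclose(zscore_panel(a * x + b), z, atol=1e-8)
        assert np.allclose(zscore_panel(-a * x + b), -z, atol=1e-8)

    def test_zero_spread_errors(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            zscore_panel([2.0, 2.0, 2.0])


@pytest.fixture(scope="module")
def null_matrix():
    cfg = SimConfig(n_coding=300, n_lncRNA=0, n_TRF=30, n_DE=0,
                    n_regulators=0, module_spec=(), n_cis_pairs=0,
                    seed=31)
    m, _, _, _ = simulate_experiment(cfg)
    return m


class TestBootstrapNull:
    def test_same_seed_gives_identical_bounds(self, null_matrix):
        m = null_matrix
        trfs = [f for f in m.feature_ids if f.startswith("TRF")]
        pool = [f for f in expressed_features(m) if f.startswith("GENE")]
        a1, b1 = rif_bootstrap_null(m, trfs, pool, n_DE=30, n_iter=200,
                                    seed=4)
        a2, b2 = rif_bootstrap_null(m, trfs, pool, n_DE=30, n_iter=200,
                                    seed=4)
        assert (a1.lower, a1.upper, b1.lower, b1.upper) == \
            (a2.lower, a2.upper, b2.lower, b2.upper)

    def test_higher_level_interval_contains_lower_level(self, null_matrix):
        m = null_matrix
        trfs = [f for f in m.feature_ids if f.startswith("TRF")]
        pool = [f for f in expressed_features(m) if f.startswith("GENE")]
        n99, _ = rif_bootstrap_null(m, trfs, pool, n_DE=30, n_iter=300,
                                    seed=5, level=0.99)
        n95, _ = rif_bootstrap_null(m, trfs, pool, n_DE=30, n_iter=300,
                                    seed=5, level=0.95)
        assert n99.lower < n95.lower and n99.upper > n95.upper

    def test_n_de_larger_than_pool_errors(self, null_matrix):
        m = null_matrix
        trfs = [f for f in m.feature_ids if f.startswith("TRF")]
        with pytest.raises(ValueError, match="pool"):
            rif_bootstrap_null(m, trfs, ["GENE000001"], n_DE=5, n_iter=100)


class TestExtremeCalls:
    def _results(self):
        return pd.DataFrame({"z1": [0.1, 3.0, -4.0], "z2": [0.2, 0.0, 2.9]},
                            index=["t0", "t1", "t2"])

    def test_interior_scores_not_flagged(self):
        null = BootstrapNull("RIF1-z", 100, 0.99, -2.5, 2.5,
                             np.zeros(1))
        out = call_extreme_trfs(self._results(), null, null)
        assert not out.loc["t0", "extreme1"]
        assert out.loc["t1", "extreme1"] and out.loc["t2", "extreme1"]
        assert out.loc["t2", "extreme2"]

    def test_infinite_bounds_flag_nothing(self):
        null = BootstrapNull("RIF1-z", 100, 0.99, -np.inf, np.inf,
                             np.zeros(1))
        out = call_extreme_trfs(self._results(), null, null)
        assert not out["extreme1"].any()
        assert not out["extreme2"].any()
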