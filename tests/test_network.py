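"""Network construction, TOM, modules, eigengenes, connectivity, hubs."""

import numpy as np
import pandas as pd
import pytest

from rifnet.network import (UNASSIGNED, build_network, detect_modules,
                            hub_lncrnas, intramodular_connectivity,
                            module_eigengene, module_trait_correlation,
                            soft_adjacency, topological_overlap)
from rifnet.data import validate_phenotype

from conftest import make_matrix


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n)
                       if u != i and u != j)
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            tom[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return tom


def random_adjacency(rng, n=10) -> pd.DataFrame:
    c = rng.uniform(-1, 1, size=(n, n))
    c = (c + c.T) / 2
    a = np.abs(c) ** 6
    np.fill_diagonal(a, 1.0)
    ids = [f"F{i}" for i in range(n)]
    return pd.DataFrame(a, index=ids, columns=ids)


class TestAdjacency:
    def test_perfectly_correlated_features_get_adjacency_one(self):
        x = np.arange(12, dtype=float) + 1
        m = make_matrix(np.vstack([x, 2 * x + 3]), 6, 6)
        adj = soft_adjacency(m, ["F0", "F1"])
        assert adj.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_half_correlation_to_the_sixth(self):
        assert 0.5 ** 6 == 0.015625  # the adjacency of r=0.5 at beta=6

    def test_matches_double_loop_evaluation(self, rng):
        x = rng.uniform(1, 10, size=(8, 12))
        m = make_matrix(x, 6, 6)
        adj = soft_adjacency(m, list(m.feature_ids), beta=6)
        for i in range(8):
            for j in range(8):
                r = np.corrcoef(x[i], x[j])[0, 1]
                expected = 1.0 if i == j else abs(r) ** 6
                assert adj.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_features_dropped(self):
        x = np.vstack([np.full(12, 5.0),
                       np.arange(12, dtype=float),
                       np.arange(12, dtype=float) ** 2])
        m = make_matrix(x, 6, 6)
        adj = soft_adjacency(m, ["F0", "F1", "F2"])
        assert list(adj.index) == ["F1", "F2"]


class TestTOM:
    def test_two_node_closed_form_tom_equals_adjacency(self):
        a = pd.DataFrame([[1.0, 0.37], [0.37, 1.0]], index=["a", "b"],
                         columns=["a", "b"])
        tom = topological_overlap(a)
        assert tom.loc["a", "b"] == pytest.approx(0.37, abs=1e-15)

    def test_complete_unit_graph_gives_maximal_overlap(self):
        n = 5
        a = np.ones((n, n))
        ids = list("abcde")
        tom = topological_overlap(pd.DataFrame(a, index=ids, columns=ids))
        assert np.allclose(tom.to_numpy(), 1.0, atol=1e-12)

    def test_matches_brute_force_triple_loop(self, rng):
        adj = random_adjacency(rng, n=10)
        tom = topological_overlap(adj)
        expected = brute_force_tom(adj.to_numpy())
        assert np.abs(tom.to_numpy() - expected).max() < 1e-12

    def test_symmetric_with_entries_in_unit_interval(self, rng):
        tom = topological_overlap(random_adjacency(rng, n=12)).to_numpy()
        assert np.allclose(tom, tom.T)
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()

    def test_asymmetric_input_rejected(self):
        a = pd.DataFrame([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(a)


class TestModuleDetection:
    def test_three_perfect_blocks_recovered_exactly(self):
        sizes = [5, 4, 3]
        n = sum(sizes)
        a = np.zeros((n, n))
        start = 0
        truth = []
        for b, s in enumerate(sizes):
            a[start:start + s, start:start + s] = 0.9
            truth += [b] * s
            start += s
        np.fill_diagonal(a, 1.0)
        ids = [f"F{i}" for i in range(n)]
        adj = pd.DataFrame(a, index=ids, columns=ids)
        labels = detect_modules(topological_overlap(adj), adjacency=adj)
        by_truth = {}
        for lab, t in zip(labels, truth):
            by_truth.setdefault(t, set()).add(lab)
        assert all(len(v) == 1 for v in by_truth.values())
        assert len({next(iter(v)) for v in by_truth.values()}) == 3
        assert labels[labels == "module-1"].size == 5  # largest first

    def test_all_equal_tom_gives_single_module(self):
        n = 6
        t = np.full((n, n), 0.5)
        np.fill_diagonal(t, 1.0)
        ids = [f"F{i}" for i in range(n)]
        labels = detect_modules(pd.DataFrame(t, index=ids, columns=ids))
        assert set(labels) == {"module-1"}

    def test_small_clusters_become_unassigned(self):
        a = np.eye(8)
        a[:5, :5] = 0.9
        np.fill_diagonal(a, 1.0)
        ids = [f"F{i}" for i in range(8)]
        adj = pd.DataFrame(a, index=ids, columns=ids)
        labels = detect_modules(topological_overlap(adj), min_size=3,
                                adjacency=adj)
        assert (labels.iloc[:5] != UNASSIGNED).all()
        assert (labels.iloc[5:] == UNASSIGNED).all()


class TestEigengene:
    def test_identical_profiles_explain_all_variance(self, rng):
        base = rng.uniform(1, 10, size=12)
        m = make_matrix(np.vstack([base, base, base]), 6, 6)
        eig, var_exp = module_eigengene(m, ["F0", "F1", "F2"])
        assert var_exp == pytest.approx(1.0, abs=1e-12)
        z = (base - base.mean()) / base.std(ddof=1)
        assert abs(np.corrcoef(eig, z)[0, 1]) == pytest.approx(1.0,
                                                               abs=1e-12)

    def test_sign_convention_mean_member_correlation_nonnegative(self, rng):
        x = rng.uniform(1, 10, size=(6, 12))
        m = make_matrix(x, 6, 6)
        eig, _ = module_eigengene(m, list(m.feature_ids))
        cors = [np.corrcoef(eig, x[i])[0, 1] for i in range(6)]
        assert np.mean(cors) >= 0

    def test_feature_order_invariance(self, rng):
        x = rng.uniform(1, 10, size=(6, 12))
        m = make_matrix(x, 6, 6)
        ids = list(m.feature_ids)
        eig1, v1 = module_eigengene(m, ids)
        eig2, v2 = module_eigengene(m, ids[::-1])
        assert np.abs(eig1.to_numpy() - eig2.to_numpy()).max() < 1e-10
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_module_below_two_members_errors(self, small_matrix):
        with pytest.raises(ValueError, match="2 members"):
            module_eigengene(small_matrix, ["F0"])


class TestTraitCorrelation:
    def test_eigengene_equal_to_imf_gives_r_one(self, small_matrix):
        imf = pd.Series(np.linspace(3, 12, 12),
                        index=small_matrix.sample_ids)
        pheno = validate_phenotype(
            pd.DataFrame({"imf": imf, "group": small_matrix.groups}))
        eig = pd.Series((imf - imf.mean()) / np.linalg.norm(imf - imf.mean()),
                        index=imf.index)
        out = module_trait_correlation({"m": eig}, pheno)
        assert out.loc["m", "trait_cor"] == pytest.approx(1.0, abs=1e-12)
        assert out.loc["m", "trait_p"] < 1e-10

    def test_permuted_phenotype_flags_at_nominal_rate(self, rng):
        """Permutation calibration of the t-transform p-value."""
        eig_vals = rng.normal(size=12)
        imf_vals = rng.normal(10, 2, size=12).clip(min=0.5)
        samples = [f"s{i}" for i in range(12)]
        eig = pd.Series(eig_vals, index=samples)
        hits = 0
        n_perm = 400
        for _ in range(n_perm):
            perm = rng.permutation(imf_vals)
            pheno = pd.DataFrame({"imf": perm,
                                  "group": ["H"] * 6 + ["L"] * 6},
                                 index=samples)
            out = module_trait_correlation({"m": eig}, pheno)
            hits += out.loc["m", "trait_p"] < 0.05
        assert hits / n_perm == pytest.approx(0.05, abs=0.03)


class TestConnectivityAndHubs:
    def test_singleton_module_has_zero_kim(self):
        a = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        labels = pd.Series(["m1", UNASSIGNED, UNASSIGNED], index=list("abc"))
        kim = intramodular_connectivity(a, labels)
        assert (kim == 0).all()

    def test_complete_module_kim_is_size_minus_one(self):
        n = 5
        a = np.ones((n, n))
        ids = [f"F{i}" for i in range(n)]
        adj = pd.DataFrame(a, index=ids, columns=ids)
        labels = pd.Series(["m1"] * n, index=ids)
        kim = intramodular_connectivity(adj, labels)
        assert (kim == n - 1).all()

    def test_matches_loop_oracle(self, rng):
        adj = random_adjacency(rng, n=10)
        labels = pd.Series(["m1"] * 5 + ["m2"] * 3 + [UNASSIGNED] * 2,
                           index=adj.index)
        kim = intramodular_connectivity(adj, labels)
        a = adj.to_numpy()
        for i, f in enumerate(adj.index):
            if labels[f] == UNASSIGNED:
                expected = 0.0
            else:
                expected = sum(a[i, j] for j, g in enumerate(adj.index)
                               if g != f and labels[g] == labels[f])
            assert kim[f] == pytest.approx(expected, abs=1e-12)

    def test_top_lncrna_is_hub(self):
        kim = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0],
                        index=["l1", "g1", "g2", "g3", "g4"])
        labels = pd.Series(["m1"] * 5, index=kim.index)
        biotypes = pd.Series({"l1": "lncRNA", "g1": "coding", "g2": "coding",
                              "g3": "coding", "g4": "coding"})
        hubs = hub_lncrnas(kim, labels, biotypes)
        assert hubs["m1"] == {"l1"}

    def test_module_without_lncrnas_has_empty_hub_set(self):
        kim = pd.Series([3.0, 2.0, 1.0], index=["g1", "g2", "g3"])
        labels = pd.Series(["m1"] * 3, index=kim.index)
        biotypes = pd.Series({g: "coding" for g in kim.index})
        assert hub_lncrnas(kim, labels, biotypes)["m1"] == set()
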