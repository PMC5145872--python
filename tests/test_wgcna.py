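"""Weighted network construction, module detection, scoring and hub calls."""

import numpy as np
import pandas as pd
import pytest

from coexkit import (
    SimConfig,
    WeightedNet,
    adjacency,
    detect_modules,
    generate_expression,
    module_eigengene,
    pick_soft_threshold,
    scale_free_fit,
    score_genes,
    select_hubs,
    topological_overlap,
)
from coexkit.study import ExpressionStudy
from coexkit.wgcna import GRAY, ModuleResult

from conftest import make_study
from oracles import scale_free_fit_oracle, tom_oracle


def _frame(values):
    return pd.DataFrame(values, index=[f"G{i}" for i in range(values.shape[0])],
                        columns=[f"S{j}" for j in range(values.shape[1])])


class TestAdjacency:
    def test_extreme_correlations_beta9(self):
        """cor = {-1, 0, 1} map to S = {0, (1/2)^9, 1} at the reference power."""
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])      # orthogonal to x
        values = np.vstack([x, 2 * x + 3, -x, y])
        net = adjacency(_frame(values), beta=9)
        assert net.S[0, 1] == pytest.approx(1.0, abs=1e-14)          # cor +1
        assert net.S[0, 2] == pytest.approx(0.0, abs=1e-14)          # cor -1
        assert net.S[0, 3] == pytest.approx(0.5 ** 9, abs=1e-14)     # cor 0
        assert net.S[0, 3] == pytest.approx(0.001953125)

    def test_beta_one_is_half_shifted_correlation(self, rng):
        values = rng.normal(size=(12, 20))
        net = adjacency(_frame(values), beta=1)
        r = np.corrcoef(values)
        off = ~np.eye(12, dtype=bool)
        np.testing.assert_allclose(net.S[off], ((1 + r) / 2)[off], atol=1e-12)

    def test_bounds_symmetry_and_diagonal(self, rng):
        net = adjacency(_frame(rng.normal(size=(15, 10))), beta=6)
        assert np.allclose(net.S, net.S.T)
        assert (net.S >= 0).all() and (net.S <= 1).all()
        assert np.allclose(np.diag(net.S), 1.0)
        assert np.allclose(net.k, net.S.sum(1) - 1.0)

    def test_zero_variance_row_adjacency(self, rng):
        values = rng.normal(size=(6, 10))
        values[2] = 4.2
        net = adjacency(_frame(values), beta=9)
        off = [i for i in range(6) if i != 2]
        np.testing.assert_allclose(net.S[2, off], 0.5 ** 9, atol=1e-14)

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            adjacency(_frame(rng.normal(size=(5, 10))), beta=0)
        with pytest.raises(ValueError):
            adjacency(_frame(rng.normal(size=(5, 2))), beta=2)


class TestTOM:
    def test_three_gene_hand_example(self):
        S = np.full((3, 3), 0.5)
        np.fill_diagonal(S, 1.0)
        net = topological_overlap(WeightedNet(genes=list("abc"), beta=1, S=S))
        # omega_12 = (0.5*0.5 + 0.5) / (min(1,1) + 1 - 0.5) = 0.75 / 1.5
        assert net.omega[0, 1] == pytest.approx(0.5, abs=1e-14)
        assert np.allclose(np.diag(net.omega), 1.0)

    def test_disconnected_adjacency(self):
        S = np.eye(4)
        net = topological_overlap(WeightedNet(genes=list("abcd"), beta=1, S=S))
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(net.omega[off], 0.0)
        assert np.allclose(net.d[off], 1.0)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(10):
            S = rng.uniform(0, 1, size=(10, 10))
            S = (S + S.T) / 2
            np.fill_diagonal(S, 1.0)
            net = topological_overlap(WeightedNet(genes=[str(i) for i in range(10)],
                                                  beta=1, S=S))
            np.testing.assert_allclose(net.omega, tom_oracle(S), atol=1e-12)
            assert (net.omega <= 1 + 1e-12).all()
            assert (net.d >= -1e-12).all() and (net.d <= 1 + 1e-12).all()


class TestSoftThreshold:
    def test_fit_matches_independent_regression(self, rng):
        values = rng.normal(size=(80, 30))
        net = adjacency(_frame(values), beta=5)
        r2, _ = scale_free_fit(net.k)
        assert r2 == pytest.approx(scale_free_fit_oracle(net.k), abs=1e-10)

    def test_positive_slope_never_reaches_target(self):
        # frequencies increasing with k: perfect fit but positive slope
        k = np.repeat([1.0, 2.0, 4.0, 8.0], [2, 4, 8, 16])
        r2, slope = scale_free_fit(k, n_bins=4)
        assert slope > 0
        assert r2 <= 0

    def test_iid_genes_flagged_as_not_reaching_target(self, rng):
        study = make_study(rng.normal(size=(60, 24)), n_case=12)
        scan = pick_soft_threshold(study, candidates=[1, 2, 3], target_r2=0.95)
        assert not scan.reached_target
        assert scan.chosen_beta in (1.0, 2.0, 3.0)
        assert len(scan.table) == 3

    def test_smallest_passing_beta_chosen(self, monkeypatch):
        import coexkit.wgcna as w
        fits = {2: 0.5, 4: 0.85, 6: 0.9}
        rng = np.random.default_rng(0)
        study = make_study(rng.normal(size=(25, 12)), n_case=6)
        monkeypatch.setattr(w, "scale_free_fit",
                            lambda k, n_bins=10, _f=fits, _c=iter([2, 4, 6]): (_f[next(_c)], -1.0))
        scan = w.pick_soft_threshold(study, candidates=[2, 4, 6], target_r2=0.8)
        assert scan.chosen_beta == 4.0
        assert scan.reached_target


def _block_net(n_per_block=35, within=0.8, between=0.01):
    n = 2 * n_per_block
    omega = np.full((n, n), between)
    omega[:n_per_block, :n_per_block] = within
    omega[n_per_block:, n_per_block:] = within
    np.fill_diagonal(omega, 1.0)
    net = WeightedNet(genes=[f"G{i}" for i in range(n)], beta=9, S=omega.copy())
    net.omega = omega
    net.d = 1 - omega
    return net


class TestModuleDetection:
    def test_two_planted_blocks_recovered(self):
        net = _block_net()
        labels = detect_modules(net, cut_height=0.99, min_module_size=30)
        first = set(labels.iloc[:35])
        second = set(labels.iloc[35:])
        assert len(first) == 1 and len(second) == 1
        assert first != second
        assert GRAY not in (first | second)

    def test_uniformly_low_overlap_all_gray(self):
        n = 50
        omega = np.full((n, n), 0.001)
        np.fill_diagonal(omega, 1.0)
        net = WeightedNet(genes=[f"G{i}" for i in range(n)], beta=9, S=omega.copy())
        net.omega = omega
        net.d = 1 - omega
        labels = detect_modules(net, cut_height=0.99, min_module_size=30)
        assert (labels == GRAY).all()

    def test_cut_height_zero_all_gray(self):
        net = _block_net()
        labels = detect_modules(net, cut_height=0.0, min_module_size=5)
        assert (labels == GRAY).all()

    def test_min_size_larger_than_universe_all_gray(self):
        net = _block_net(n_per_block=10)
        labels = detect_modules(net, min_module_size=100)
        assert (labels == GRAY).all()

    def test_color_labels_by_size_rank(self):
        n1, n2 = 40, 32
        n = n1 + n2 + 10
        omega = np.full((n, n), 0.001)
        omega[:n1, :n1] = 0.8
        omega[n1:n1 + n2, n1:n1 + n2] = 0.8
        np.fill_diagonal(omega, 1.0)
        net = WeightedNet(genes=[f"G{i}" for i in range(n)], beta=9, S=omega.copy())
        net.omega = omega
        net.d = 1 - omega
        labels = detect_modules(net, min_module_size=30)
        assert set(labels.iloc[:n1]) == {"turquoise"}
        assert set(labels.iloc[n1:n1 + n2]) == {"blue"}
        assert (labels.iloc[n1 + n2:] == GRAY).all()


class TestEigengene:
    def test_rank_one_module(self):
        v = np.array([1.0, -2.0, 0.5, 3.0, -1.5, 0.2])
        values = np.vstack([v, 2 * v + 1, -0.5 * v + 4][:2])  # two scaled copies
        frame = _frame(values)
        me = module_eigengene(frame, ["G0", "G1"])
        assert abs(np.corrcoef(me, v)[0, 1]) == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(me) == pytest.approx(1.0)

    def test_sign_orientation(self, rng):
        values = rng.normal(size=(5, 12))
        frame = _frame(values)
        me = module_eigengene(frame, frame.index.tolist())
        cors = [np.corrcoef(me, row)[0, 1] for row in values]
        assert np.mean(cors) >= 0
        me_neg = module_eigengene(-frame, frame.index.tolist())
        cors_neg = [np.corrcoef(me_neg, row)[0, 1] for row in -values]
        assert np.mean(cors_neg) >= 0

    def test_planted_factor_recovered(self):
        cfg = SimConfig(n_genes=40, n_samples_per_group=(20, 20), n_modules=1,
                        module_size=40, loading_range=(0.8, 1.0), noise_sd=0.5,
                        de_effect=0.0, de_fraction=0.0, de_module=None, seed=2)
        study, truth = generate_expression(cfg)
        me = module_eigengene(study.values, truth.module_genes("M1"))
        f = truth.latent_factors.loc["M1"]
        assert abs(np.corrcoef(me, f)[0, 1]) >= 0.9

    def test_rank_zero_module_rejected(self):
        values = np.ones((3, 8))
        with pytest.raises(ValueError, match="rank 0"):
            module_eigengene(_frame(values), ["G0", "G1", "G2"])


class TestScores:
    @pytest.fixture(scope="class")
    @staticmethod
    def scored():
        cfg = SimConfig(n_genes=150, n_samples_per_group=(20, 20), n_modules=2,
                        module_size=40, loading_range=(0.7, 1.0), noise_sd=0.5,
                        de_effect=1.5, de_module=0, seed=4)
        study, truth = generate_expression(cfg)
        net = topological_overlap(adjacency(study, beta=9))
        partition = detect_modules(net, min_module_size=20)
        return study, truth, net, partition, score_genes(study, net, partition)

    def test_gene_equal_to_trait_has_gs_one(self, rng):
        n = 16
        values = rng.normal(size=(10, n))
        values[0] = np.r_[np.ones(8), np.zeros(8)]
        study = make_study(values, n_case=8)
        net = topological_overlap(adjacency(study, beta=2))
        partition = pd.Series(GRAY, index=study.gene_ids)
        result = score_genes(study, net, partition)
        assert result.gs.loc["G0"] == pytest.approx(1.0, abs=1e-12)

    def test_ic_is_within_module_adjacency_sum(self):
        S = np.array([
            [1.0, 0.5, 0.5, 0.5],
            [0.5, 1.0, 0.2, 0.3],
            [0.5, 0.2, 1.0, 0.4],
            [0.5, 0.3, 0.4, 1.0],
        ])
        net = WeightedNet(genes=["a", "b", "c", "d"], beta=1, S=S)
        rng = np.random.default_rng(0)
        values = rng.normal(size=(4, 10))
        study = make_study(values, n_case=5, prefix="X")
        study.values.index = ["a", "b", "c", "d"]
        partition = pd.Series("turquoise", index=["a", "b", "c", "d"])
        result = score_genes(study, net, partition)
        assert result.ic.loc["a"] == pytest.approx(1.5)

    def test_mm_equals_plain_correlation(self, scored):
        study, _, _, partition, result = scored
        module = result.modules[0]
        me = result.me.loc[module].to_numpy()
        for gene in result.genes_of(module)[:10]:
            expected = np.corrcoef(study.values.loc[gene], me)[0, 1]
            assert result.mm.loc[gene, module] == pytest.approx(expected, abs=1e-10)

    def test_within_module_mm_exceeds_cross(self, scored):
        _, truth, _, _, result = scored
        if len(result.modules) < 2:
            pytest.skip("fixture did not split modules")
        m1, m2 = result.modules[:2]
        within = result.mm.loc[result.genes_of(m1), m1].abs().mean()
        cross = result.mm.loc[result.genes_of(m1), m2].abs().mean()
        assert within > cross

    def test_de_module_has_top_trait_correlation(self, scored):
        _, truth, _, partition, result = scored
        de_mod = truth.module_of_gene[truth.de_effect_of_gene.index[0]]
        members = set(truth.module_genes(de_mod))
        overlaps = {m: len(set(result.genes_of(m)) & members) for m in result.modules}
        detected = max(overlaps, key=overlaps.get)
        cors = result.module_trait["cor"].abs()
        assert cors.idxmax() == detected

    def test_constant_trait_rejected(self, scored):
        study, _, net, partition, _ = scored
        trait = pd.Series(1, index=study.sample_ids)
        with pytest.raises(ValueError, match="constant"):
            score_genes(study, net, partition, trait=trait)

    def test_sample_permutation_invariance(self, scored):
        study, _, net, partition, result = scored
        perm = np.random.default_rng(1).permutation(study.n_samples)
        cols = [study.sample_ids[i] for i in perm]
        shuffled = ExpressionStudy(study.values[cols], study.groups[cols])
        result2 = score_genes(shuffled, net, partition)
        pd.testing.assert_series_equal(result.gs, result2.gs, atol=1e-10)
        pd.testing.assert_series_equal(result.ic, result2.ic, atol=1e-10)
        np.testing.assert_allclose(result.module_trait["cor"].abs(),
                                   result2.module_trait["cor"].abs(), atol=1e-10)


class TestHubs:
    def _result(self):
        genes = ["a", "b", "c", "d"]
        partition = pd.Series("blue", index=genes)
        mm = pd.DataFrame({"blue": [0.95, 0.90, 0.92, 0.40]}, index=genes)
        result = ModuleResult(module_of_gene=partition, mm=mm,
                              ic=pd.Series([3.0, 2.0, 2.5, 0.5], index=genes),
                              gs=pd.Series([0.5, 0.4, 0.6, 0.1], index=genes))
        S = np.full((4, 4), 0.3)
        np.fill_diagonal(S, 1.0)
        net = WeightedNet(genes=genes, beta=1, S=S)
        return result, net

    def test_strict_mm_threshold(self):
        result, net = self._result()
        table = select_hubs(result, net, ["blue"], mm_thr=0.9)
        assert bool(table.loc["a", "hub"]) and bool(table.loc["c", "hub"])
        assert not table.loc["b", "hub"]     # MM == 0.9 exactly: strict >
        assert not table.loc["d", "hub"]
        assert table.index.tolist() == ["a", "c", "b", "d"]   # MM descending

    def test_empty_module_section_not_error(self):
        result, net = self._result()
        table = select_hubs(result, net, ["blue"], mm_thr=0.99)
        assert len(table) == 4 and not table["hub"].any()
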