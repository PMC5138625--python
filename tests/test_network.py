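"""Signed co-expression network: preprocessing through hub extraction."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from lincnet.network import (
    ModuleAssignment,
    PreprocessConfig,
    cluster_and_cut,
    connectivity,
    correlation_pvalue,
    kme_and_hubs,
    kme_table,
    merge_modules,
    module_eigengenes,
    module_stage_stats,
    pick_soft_threshold,
    preprocess,
    signed_adjacency,
    stage_specific_modules,
    tom_similarity,
)


def _expr(rows: dict, n_samples: int | None = None) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return df


def _block_expr(rng, n_blocks=2, per_block=20, n_samples=10, noise=0.01):
    rows = {}
    for b in range(n_blocks):
        base = rng.standard_normal(n_samples) * 2
        for g in range(per_block):
            rows[f"b{b}g{g}"] = base + noise * rng.standard_normal(n_samples)
    return _expr(rows)


class TestPreprocess:
    def test_low_expression_gene_dropped(self):
        df = pd.DataFrame({"s1": [0.04, 5.0], "s2": [0.01, 7.0]}, index=["low", "hi"])
        out = preprocess(df)
        assert "low" not in out.index and "hi" in out.index

    def test_top_75_percent_by_variance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {f"s{i}": np.arange(8) * rng.uniform(0.5, 2) + 1 for i in range(4)},
            index=[f"g{i}" for i in range(8)],
        )
        assert len(preprocess(df)) == 6  # 8 genes -> top 75% = 6

    def test_log2_offset_one(self):
        df = pd.DataFrame({"s1": [3.0], "s2": [0.1]}, index=["g"])
        out = preprocess(df, PreprocessConfig(variance_quantile_kept=1.0))
        assert out.loc["g", "s1"] == pytest.approx(2.0)  # log2(3 + 1)

    def test_all_dropped_is_an_error(self):
        df = pd.DataFrame({"s1": [0.01], "s2": [0.02]}, index=["g"])
        with pytest.raises(ValueError):
            preprocess(df)


class TestAdjacency:
    def test_analytic_anchors(self):
        # perfectly correlated, anticorrelated and orthogonal profiles
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])  # exactly uncorrelated with x
        expr = _expr({"up": x, "down": -x, "orth": y})
        adj = signed_adjacency(expr, 13)
        assert adj.loc["up", "down"] == pytest.approx(0.0, abs=1e-12)
        assert adj.loc["up", "orth"] == pytest.approx(0.5**13, abs=1e-12)
        assert adj.loc["up", "up"] == 1.0

    def test_symmetry_and_range(self, bundle):
        expr = preprocess(bundle.stage_matrix).iloc[:60]
        adj = signed_adjacency(expr, 13)
        assert np.allclose(adj.values, adj.values.T)
        assert adj.values.min() >= 0 and adj.values.max() <= 1

    def test_zero_variance_gene_named_in_error(self):
        expr = _expr({"flat": np.ones(5), "ok": np.arange(5.0)})
        with pytest.raises(ValueError, match="flat"):
            signed_adjacency(expr, 13)

    def test_mean_connectivity_decreases_with_power(self, bundle):
        expr = preprocess(bundle.stage_matrix).iloc[:50]
        ks = [connectivity(signed_adjacency(expr, b)).mean() for b in (1, 5, 13, 20)]
        assert all(a > b for a, b in zip(ks, ks[1:]))


class TestTOM:
    def test_complete_graph_gives_all_ones(self):
        n = 6
        adj = pd.DataFrame(np.ones((n, n)), index=range(n), columns=range(n))
        tom = tom_similarity(adj)
        assert np.allclose(tom.values, 1.0)

    def test_empty_graph_gives_zero_overlap(self):
        n = 5
        adj = pd.DataFrame(np.eye(n), index=range(n), columns=range(n))
        tom = tom_similarity(adj)
        off = tom.values[~np.eye(n, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_matches_cubic_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(6, 11))
            a = rng.uniform(0, 1, (n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = tom_similarity(pd.DataFrame(a)).values
            a0 = a.copy()
            np.fill_diagonal(a0, 0.0)
            k = a0.sum(axis=1)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        assert tom[i, j] == 1.0
                        continue
                    l = sum(a0[i, u] * a0[u, j] for u in range(n) if u not in (i, j))
                    expected = (l + a0[i, j]) / (min(k[i], k[j]) + 1 - a0[i, j])
                    assert abs(tom[i, j] - expected) < 1e-12

    def test_symmetric_bounded(self, bundle):
        expr = preprocess(bundle.stage_matrix).iloc[:60]
        tom = tom_similarity(signed_adjacency(expr, 13))
        assert np.allclose(tom.values, tom.values.T)
        assert tom.values.min() >= 0 and tom.values.max() <= 1 + 1e-12


class TestSoftThreshold:
    def test_hub_continuum_reaches_target_with_smallest_power(self):
        """A network with few strong and many weak memberships is scale-free."""
        rng = np.random.default_rng(7)
        e = rng.standard_normal(12)
        w = rng.uniform(0.05, 1.0, 150) ** 2
        X = w[:, None] * e + np.sqrt(1 - w[:, None] ** 2) * rng.standard_normal((150, 12))
        fit = pick_soft_threshold(_expr({f"g{i}": X[i] for i in range(150)}))
        assert fit.reached_target
        below = fit.fit_table.loc[: fit.beta - 1, "signed_r2"]
        assert (below < 0.9).all()

    def test_pure_noise_takes_fallback_warning_path(self):
        rng = np.random.default_rng(1)
        expr = _expr({f"g{i}": rng.standard_normal(10) for i in range(40)})
        with pytest.warns(UserWarning, match="no power reached"):
            fit = pick_soft_threshold(expr)
        assert not fit.reached_target


class TestClustering:
    def test_two_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(5)
        expr = _block_expr(rng, n_blocks=2, per_block=20)
        tom = tom_similarity(signed_adjacency(expr, 13))
        _, assignment = cluster_and_cut(tom, min_module_size=10)
        truth = [g[:2] for g in expr.index]
        assert adjusted_rand_score(truth, assignment.labels.tolist()) == 1.0
        assert len(assignment.module_ids) == 2

    def test_identical_profiles_form_single_module(self):
        base = np.arange(10.0)
        expr = _expr({f"g{i}": base for i in range(15)})
        # all-equal profiles: correlation 1 everywhere, one block
        adj = pd.DataFrame(np.ones((15, 15)), index=expr.index, columns=expr.index)
        _, assignment = cluster_and_cut(tom_similarity(adj), min_module_size=5)
        assert len(assignment.module_ids) == 1
        assert assignment.sizes().iloc[0] == 15

    def test_pure_noise_leaves_majority_unassigned(self):
        counts = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            expr = _expr({f"g{i}": rng.standard_normal(10) for i in range(60)})
            tom = tom_similarity(signed_adjacency(expr, 13))
            # strict settings: low cut height, sizeable minimum module
            _, assignment = cluster_and_cut(tom, min_module_size=10,
                                            cut_height_quantile=0.5)
            counts.append((assignment.labels == "unassigned").mean())
        assert np.median(counts) > 0.5

    def test_module_recovery_on_default_panel(self, bundle):
        expr = preprocess(bundle.stage_matrix)
        tom = tom_similarity(signed_adjacency(expr, 13))
        _, assignment = cluster_and_cut(tom, min_module_size=10)
        assignment = merge_modules(expr, assignment)
        truth = [bundle.truth.module_label[g] for g in expr.index]
        assert adjusted_rand_score(truth, assignment.labels.tolist()) >= 0.9


class TestEigengenes:
    def test_identical_profiles_perfectly_represented(self):
        base = np.sin(np.arange(8.0))
        expr = _expr({f"g{i}": base + 0.001 * i for i in range(6)})
        assignment = ModuleAssignment(pd.Series("M1", index=expr.index))
        eg = module_eigengenes(expr, assignment)
        e = eg.values.loc["M1"].values
        assert abs(np.corrcoef(e, base)[0, 1]) == pytest.approx(1.0, abs=1e-4)
        assert np.corrcoef(e, base)[0, 1] > 0  # orientation rule
        assert eg.explained_variance.loc["M1"] > 0.99

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((8, 10))
        expr = _expr({f"g{i}": X[i] for i in range(8)})
        assignment = ModuleAssignment(pd.Series("M1", index=expr.index))
        e1 = module_eigengenes(expr, assignment).values.loc["M1"]
        e2 = module_eigengenes(-expr, assignment).values.loc["M1"]
        # orientation keeps each eigengene aligned with its module mean
        m1 = expr.values.mean(axis=0)
        assert np.corrcoef(e1, (expr.values - expr.values.mean(1, keepdims=True)).mean(0))[0, 1] >= 0

    def test_matches_independent_svd_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((12, 9))
        expr = _expr({f"g{i}": X[i] for i in range(12)})
        assignment = ModuleAssignment(pd.Series("M1", index=expr.index))
        e = module_eigengenes(expr, assignment).values.loc["M1"].values
        Z = stats.zscore(X, axis=1, ddof=0)
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        oracle = vt[0]
        assert min(np.abs(e - oracle).max(), np.abs(e + oracle).max()) < 1e-10

    def test_unit_norm(self, bundle):
        expr = preprocess(bundle.stage_matrix)
        tom = tom_similarity(signed_adjacency(expr, 13))
        _, assignment = cluster_and_cut(tom, min_module_size=10)
        eg = module_eigengenes(expr, assignment)
        assert np.allclose(np.linalg.norm(eg.values.values, axis=1), 1.0)


class TestMerging:
    def _two_close_modules(self, rho):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(12)
        other = rho * base + np.sqrt(1 - rho**2) * rng.standard_normal(12)
        rows = {}
        for g in range(10):
            rows[f"a{g}"] = base + 0.05 * rng.standard_normal(12)
        for g in range(10):
            rows[f"b{g}"] = other + 0.05 * rng.standard_normal(12)
        expr = _expr(rows)
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=expr.index)
        return expr, ModuleAssignment(labels)

    def test_high_correlation_pair_merged(self):
        expr, assignment = self._two_close_modules(rho=0.95)
        merged = merge_modules(expr, assignment, threshold=0.7)
        assert len(merged.module_ids) == 1

    def test_moderate_correlation_pair_kept(self):
        expr, assignment = self._two_close_modules(rho=0.3)
        merged = merge_modules(expr, assignment, threshold=0.7)
        assert len(merged.module_ids) == 2

    def test_merging_is_idempotent(self, bundle):
        expr = preprocess(bundle.stage_matrix)
        tom = tom_similarity(signed_adjacency(expr, 13))
        _, assignment = cluster_and_cut(tom, min_module_size=10)
        once = merge_modules(expr, assignment)
        twice = merge_modules(expr, once)
        assert once.labels.equals(twice.labels)


class TestStageStats:
    def test_correlation_pvalue_anchor(self):
        # r = 0.9, n = 12: t ~ 6.53, two-sided p ~ 6e-5
        p = correlation_pvalue(0.9, 12)
        t = 0.9 * np.sqrt(10) / np.sqrt(1 - 0.81)
        assert p == pytest.approx(2 * stats.t.sf(t, 10), rel=1e-12)
        assert p < 1e-4

    def test_indicator_eigengene_is_stage_specific(self):
        samples = [f"s{i}" for i in range(12)]
        stages = pd.Series(sum([[f"st{j}"] * 2 for j in range(6)], []), index=samples)
        indicator = (stages == "st2").astype(float)
        eg_values = pd.DataFrame([indicator.values], index=["M1"], columns=samples)
        from lincnet.network import Eigengenes

        eg = Eigengenes(eg_values, pd.Series({"M1": 1.0}))
        table = module_stage_stats(eg, stages)
        hits = stage_specific_modules(table)
        assert list(hits["stage"]) == ["st2"]
        assert hits["r"].iloc[0] == pytest.approx(1.0)

    def test_planted_stage_associations_recovered(self, bundle):
        expr = preprocess(bundle.stage_matrix)
        tom = tom_similarity(signed_adjacency(expr, 13))
        _, assignment = cluster_and_cut(tom, min_module_size=10)
        assignment = merge_modules(expr, assignment)
        eg = module_eigengenes(expr, assignment)
        hits = stage_specific_modules(module_stage_stats(eg, bundle.stage_design))
        # each planted module's peak stage must be called for some detected module
        called = set(hits["stage"])
        assert set(bundle.truth.stage_of_module.values()) <= called

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            correlation_pvalue(0.5, 2)


class TestHubs:
    def test_gene_equal_to_eigengene_has_kme_one(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(10)
        expr = _expr({"hub": base, **{f"g{i}": base + 0.2 * rng.standard_normal(10) for i in range(6)}})
        assignment = ModuleAssignment(pd.Series("M1", index=expr.index))
        eg = module_eigengenes(expr, assignment)
        kme = kme_table(expr, eg)
        e = eg.values.loc["M1"].values
        manual = np.corrcoef(expr.loc["hub"].values, e)[0, 1]
        assert kme.loc["hub", "M1"] == pytest.approx(manual, abs=1e-12)
        assert kme.loc["hub", "M1"] > 0.97

    def test_orthogonal_gene_has_near_zero_kme(self):
        base = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        orth = np.array([1.0, 1, -1, -1, 1, 1, -1, -1])
        expr = _expr({"a": base, "b": base * 2, "c": orth})
        assignment = ModuleAssignment(pd.Series({"a": "M1", "b": "M1", "c": "unassigned"}))
        eg = module_eigengenes(expr, assignment)
        kme = kme_table(expr, eg)
        assert abs(kme.loc["c", "M1"]) < 1e-10

    def test_ranking_and_top_n(self, bundle):
        expr = preprocess(bundle.stage_matrix)
        tom = tom_similarity(signed_adjacency(expr, 13))
        _, assignment = cluster_and_cut(tom, min_module_size=10)
        assignment = merge_modules(expr, assignment)
        eg = module_eigengenes(expr, assignment)
        table = kme_and_hubs(expr, eg, assignment, top_n=7,
                             lincrna_ids=bundle.truth.lincrna_ids)
        for module, group in table.groupby("module"):
            assert len(group) <= 7
            assert list(group.sort_values("rank")["kme"]) == sorted(group["kme"], reverse=True)

    def test_planted_hubs_rank_in_top_decile(self, bundle):
        expr = preprocess(bundle.stage_matrix)
        tom = tom_similarity(signed_adjacency(expr, 13))
        _, assignment = cluster_and_cut(tom, min_module_size=10)
        assignment = merge_modules(expr, assignment)
        eg = module_eigengenes(expr, assignment)
        kme = kme_table(expr, eg)
        hits = total = 0
        for module in assignment.module_ids:
            members = assignment.members(module)
            decile = max(1, len(members) // 10)
            ranked = sorted(members, key=lambda g: -kme.loc[g, module])
            top = set(ranked[:decile])
            planted = [g for g in members if bundle.truth.hub_flag.get(g)]
            hits += sum(g in top for g in planted)
            total += len(planted)
        assert total > 0 and hits / total >= 0.8
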