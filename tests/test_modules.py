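import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from conftest import bh_oracle
from xenatlas.io import CountMatrix, ExpressionMatrix, ValidationError
from xenatlas.modules import (
    FuzzyClustering,
    classify_modules,
    find_stage_degs,
    fuzzy_cmeans,
    module_score,
    resampling_stage_test,
    shared_gene_frequency,
    stage_average,
)
from xenatlas.normalize import lognormalize


def expr_from_dense(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(
        sp.csr_matrix(arr),
        pd.Index([f"bc{i}" for i in range(arr.shape[0])]),
        pd.Index(genes),
        "log2cp10k",
    )


def stage_meta(em, stages):
    return pd.DataFrame({"stage": stages}, index=em.barcodes)


class TestFindStageDEGs:
    def simulate_two_stages(self, seed, n_cells=300, shift_gene_fold=2.0):
        rng = np.random.default_rng(seed)
        n_genes = 30
        mu = rng.lognormal(1.0, 0.5, n_genes)
        a = rng.poisson(mu, size=(n_cells, n_genes))
        mu2 = mu.copy()
        mu2[0] *= shift_gene_fold
        b = rng.poisson(mu2, size=(n_cells, n_genes))
        counts = np.vstack([a, b]) + 0  # keep ints
        counts[:, 1] += 1  # ensure no zero-total cells
        cm = CountMatrix(
            sp.csr_matrix(counts),
            pd.Index([f"bc{i}" for i in range(2 * n_cells)]),
            pd.Index([f"g{j}" for j in range(n_genes)]),
        )
        cm.meta["stage"] = ["NF48"] * n_cells + ["NF54"] * n_cells
        return lognormalize(cm), cm.meta

    def test_low_detection_gene_excluded_regardless_of_effect(self):
        # gene 0 detected in 5% of cells in both stages but with a huge shift
        rng = np.random.default_rng(0)
        arr = np.zeros((200, 3))
        arr[:, 1] = 1.0
        hot = rng.choice(100, 5, replace=False)
        arr[hot, 0] = 6.0
        em = expr_from_dense(arr)
        meta = stage_meta(em, ["NF48"] * 100 + ["NF54"] * 100)
        degs = find_stage_degs(em, meta, "NF48", "NF54", min_pct=0.1)
        assert "g0" not in degs

    def test_identical_expression_excluded(self):
        arr = np.tile([1.0, 2.0], (20, 1))
        em = expr_from_dense(arr)
        meta = stage_meta(em, ["NF48"] * 10 + ["NF54"] * 10)
        assert len(find_stage_degs(em, meta, "NF48", "NF54")) == 0

    def test_planted_twofold_shift_detected_across_seeds(self):
        hits = 0
        for seed in range(20):
            em, meta = self.simulate_two_stages(seed)
            degs = find_stage_degs(em, meta, "NF48", "NF54")
            hits += "g0" in degs
        assert hits >= 19  # >= 95% of 20 seeds

    def test_tiny_stage_rejected(self):
        em = expr_from_dense(np.ones((4, 2)))
        meta = stage_meta(em, ["NF48", "NF48", "NF54", "NF59"])
        with pytest.raises(ValidationError, match="< 3"):
            find_stage_degs(em, meta, "NF48", "NF54")


class TestStageAverage:
    def test_single_cell_per_stage_is_delog_relog(self):
        arr = np.array([[1.0, 3.0], [2.0, 0.0]])
        em = expr_from_dense(arr)
        meta = stage_meta(em, ["NF48", "NF54"])
        prof, dropped = stage_average(em, meta, ["NF48", "NF54"], standardize=False)
        expected = np.log2((np.exp2(arr) - 1) + 1)  # identity back to the log values
        np.testing.assert_allclose(prof.to_numpy(), expected.T)

    def test_constant_gene_dropped_when_standardizing(self, caplog):
        import logging

        arr = np.array([[1.0, 3.0], [1.0, 0.0]])
        em = expr_from_dense(arr)
        meta = stage_meta(em, ["NF48", "NF54"])
        with caplog.at_level(logging.WARNING, logger="xenatlas"):
            prof, dropped = stage_average(em, meta, ["NF48", "NF54"])
        assert dropped.tolist() == ["g0"]
        assert "constant" in caplog.text

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(10)
        arr = rng.random((9, 5)) * 3
        em = expr_from_dense(arr)
        stages = ["NF48"] * 3 + ["NF54"] * 3 + ["NF59"] * 3
        meta = stage_meta(em, stages)
        prof, _ = stage_average(em, meta, ["NF48", "NF54", "NF59"], standardize=False)
        for j in range(5):
            for s, rows in (("NF48", [0, 1, 2]), ("NF54", [3, 4, 5]), ("NF59", [6, 7, 8])):
                vals = [2 ** arr[i, j] - 1 for i in rows]
                expected = np.log2(sum(vals) / 3 + 1)
                assert prof.iloc[j][s] == pytest.approx(expected)

    def test_empty_stage_rejected(self):
        em = expr_from_dense(np.ones((2, 2)))
        meta = stage_meta(em, ["NF48", "NF48"])
        with pytest.raises(ValidationError):
            stage_average(em, meta, ["NF48", "NF54"])


class TestFuzzyCMeans:
    def test_equidistant_point_has_symmetric_membership(self):
        X = pd.DataFrame(
            [[-1.0, 0.0], [1.0, 0.0]] * 10 + [[0.0, 0.0]],
            index=[f"g{i}" for i in range(21)],
        )
        fc = fuzzy_cmeans(X, c=2, seed=0)
        u = fc.membership.loc["g20"].to_numpy()
        np.testing.assert_allclose(u, [0.5, 0.5], atol=0.01)

    def test_membership_rows_sum_to_one_and_objective_monotone(self):
        rng = np.random.default_rng(11)
        for seed in range(50):
            X = pd.DataFrame(rng.standard_normal((40, 4)))
            X.index = [f"g{i}" for i in range(40)]
            fc = fuzzy_cmeans(X, c=3, seed=seed)
            np.testing.assert_allclose(fc.membership.sum(axis=1), 1.0, atol=1e-9)
            obj = np.asarray(fc.objectives)
            assert (np.diff(obj) <= 1e-9 * np.maximum(obj[:-1], 1.0)).all()

    def test_two_separated_bundles_recovered_sharply(self):
        rng = np.random.default_rng(12)
        up = np.array([-1.16, -0.39, 0.39, 1.16])
        down = -up
        X = np.vstack([
            up + 0.05 * rng.standard_normal((100, 4)),
            down + 0.05 * rng.standard_normal((100, 4)),
        ])
        Xdf = pd.DataFrame(X, index=[f"g{i}" for i in range(200)])
        fc = fuzzy_cmeans(Xdf, c=2, seed=1)
        maxmem = fc.membership.max(axis=1)
        assert (maxmem > 0.9).mean() >= 0.99
        hard = fc.hard_assignment()
        assert hard.iloc[:100].nunique() == 1 and hard.iloc[100:].nunique() == 1
        assert hard.iloc[0] != hard.iloc[150]

    def test_non_finite_input_rejected(self):
        X = pd.DataFrame([[np.nan, 0.0], [1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValidationError):
            fuzzy_cmeans(X, c=2)

    def test_bad_cluster_count_rejected(self):
        X = pd.DataFrame(np.eye(3))
        with pytest.raises(ValidationError):
            fuzzy_cmeans(X, c=3)


class TestModuleScore:
    def test_control_pool_identical_to_gene_set_scores_zero(self):
        rng = np.random.default_rng(13)
        em = expr_from_dense(rng.random((10, 3)))
        s = module_score(em, ["g0", "g1", "g2"], n_bins=1, n_ctrl=10, seed=0)
        np.testing.assert_allclose(s.to_numpy(), 0.0, atol=1e-12)

    def test_shift_invariance_per_cell(self):
        rng = np.random.default_rng(14)
        arr = rng.random((6, 8))
        em1 = expr_from_dense(arr)
        em2 = expr_from_dense(arr + 0.7)  # constant added to every gene of every cell
        s1 = module_score(em1, ["g0", "g3"], n_bins=2, n_ctrl=100, seed=5)
        s2 = module_score(em2, ["g0", "g3"], n_bins=2, n_ctrl=100, seed=5)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-9)

    def test_three_gene_toy_matches_hand_computation(self):
        arr = np.array([[1.0, 2.0, 6.0], [0.0, 1.0, 2.0]])
        em = expr_from_dense(arr)
        s = module_score(em, ["g2"], n_bins=1, n_ctrl=10, seed=0)
        # controls = all three genes; score = x_g2 - mean(all)
        np.testing.assert_allclose(s.to_numpy(), [6 - 3.0, 2 - 1.0])

    def test_empty_gene_set_rejected(self):
        em = expr_from_dense(np.ones((2, 2)))
        with pytest.raises(ValidationError):
            module_score(em, [])


class TestResampling:
    def scores_for(self, rng, n, shift=0.0):
        a = rng.standard_normal(n)
        b = rng.standard_normal(n) + shift
        s = pd.Series(np.concatenate([a, b]), index=[f"bc{i}" for i in range(2 * n)])
        meta = pd.DataFrame({"stage": ["NF48"] * n + ["NF54"] * n}, index=s.index)
        return s, meta

    def test_null_distribution_gives_large_averaged_p(self):
        rng = np.random.default_rng(15)
        ok = 0
        for _ in range(10):
            s, meta = self.scores_for(rng, 300)
            p = resampling_stage_test(s, meta, "NF48", n_tests=50, seed=1)
            ok += p["NF54"] >= 0.2
        assert ok >= 9

    def test_strong_shift_gives_tiny_averaged_p(self):
        rng = np.random.default_rng(16)
        s, meta = self.scores_for(rng, 500, shift=2.0)  # 2 pooled SDs
        p = resampling_stage_test(s, meta, "NF48", n_tests=50, seed=1)
        assert p["NF54"] < 1e-20

    def test_single_test_reproducible_with_seed(self):
        rng = np.random.default_rng(17)
        s, meta = self.scores_for(rng, 200, shift=0.3)
        p1 = resampling_stage_test(s, meta, "NF48", n_tests=1, seed=9)
        p2 = resampling_stage_test(s, meta, "NF48", n_tests=1, seed=9)
        assert p1["NF54"] == p2["NF54"]

    def test_small_stage_warns_and_uses_available_cells(self, caplog):
        import logging

        rng = np.random.default_rng(18)
        s, meta = self.scores_for(rng, 50)
        with caplog.at_level(logging.WARNING, logger="xenatlas"):
            resampling_stage_test(s, meta, "NF48", n_tests=5, seed=0)
        assert "using all of them" in caplog.text

    def test_under_three_cells_rejected(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        meta = pd.DataFrame({"stage": ["NF48", "NF48", "NF48", "NF54"]}, index=s.index)
        with pytest.raises(ValidationError):
            resampling_stage_test(s, meta, "NF48", n_tests=2)


class TestClassification:
    def planted_run(self, seed, archetypes=(1, 2, 3, 4)):
        from xenatlas.simulate import AtlasConfig, generate_atlas
        from xenatlas.modules import stage_average

        cfg = AtlasConfig(
            lineages={"gut": 800}, n_genes=130, n_tfs=0, planted_tfs_per_lineage=0,
            module_genes_per_archetype=25, gene_on_prob=1.0,
            ambient_fraction=0.0, n_empty_barcodes=0, seed=seed,
        )
        cm, truth = generate_atlas(cfg)
        em = lognormalize(cm)
        stages = list(cfg.stages)
        prof, _ = stage_average(em, cm.meta, stages)
        fc = fuzzy_cmeans(prof, c=6, seed=seed)
        hard = fc.hard_assignment()
        scores = {
            cl: module_score(em, hard.index[hard == cl], seed=seed + 3)
            for cl in sorted(hard.unique())
        }
        asg = classify_modules(fc, scores, cm.meta, stages, n_tests=60, seed=seed)
        return truth, fc, asg

    def test_planted_archetypes_recovered_and_modules_exclusive(self):
        truth, fc, asg = self.planted_run(21)
        arch = truth.module_archetype
        hard = fc.hard_assignment()
        # planted genes land in their own module
        correct = np.mean([asg.gene_module[g] == a for g, a in arch.items()])
        assert correct >= 0.9
        # climax-peak and climax-trough never co-assigned
        assert all(m in (1, 2, 3, 4, "unassigned") for m in asg.cluster_module.values())

    def test_flat_null_cluster_stays_unassigned(self):
        rng = np.random.default_rng(22)
        n = 1200
        em = expr_from_dense(rng.random((n, 40)))
        meta = pd.DataFrame(
            {"stage": np.repeat(["NF48", "NF54", "NF59", "NF66"], n // 4)},
            index=em.barcodes,
        )
        prof, _ = stage_average(em, meta, ["NF48", "NF54", "NF59", "NF66"])
        fc = fuzzy_cmeans(prof, c=3, seed=2)
        hard = fc.hard_assignment()
        scores = {
            cl: module_score(em, hard.index[hard == cl], seed=3)
            for cl in sorted(hard.unique())
        }
        asg = classify_modules(fc, scores, meta, ["NF48", "NF54", "NF59", "NF66"],
                               n_tests=40, seed=4)
        assert all(v == "unassigned" for v in asg.cluster_module.values())
        assert not any(asg.significant.values())

    def test_missing_climax_stage_rejected(self):
        fc = FuzzyClustering(
            centers=pd.DataFrame(np.zeros((2, 3)), index=["c00", "c01"]),
            membership=pd.DataFrame(
                [[1.0, 0.0], [0.0, 1.0]], index=["g0", "g1"], columns=["c00", "c01"]
            ),
            fuzzifier=1.25, n_iter=1, objective=0.0, objectives=[0.0],
        )
        with pytest.raises(ValidationError, match="climax"):
            classify_modules(fc, {}, pd.DataFrame(), ["NF48", "NF54", "NF59"],
                             climax_stage="NF99")


def test_bh_adjustment_matches_step_up_oracle():
    from xenatlas.enrich import bh_adjust

    rng = np.random.default_rng(23)
    for _ in range(100):
        p = rng.random(rng.integers(1, 40))
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


class TestSharedGeneFrequency:
    def test_gene_in_every_cell_type_counts_all(self):
        mods = {f"ct{i}": {1: {"zan"}} for i in range(5)}
        out = shared_gene_frequency(mods)
        row = out[(out.gene == "zan") & (out.module == 1)]
        assert row["freq"].iloc[0] == 5

    def test_absent_gene_not_reported(self):
        out = shared_gene_frequency({"ct": {1: {"a"}}})
        assert "b" not in set(out.gene)

    def test_matches_brute_force_nested_loop(self):
        rng = np.random.default_rng(24)
        genes = [f"g{i}" for i in range(10)]
        mods = {
            f"ct{i}": {m: set(rng.choice(genes, 4, replace=False)) for m in (1, 2)}
            for i in range(4)
        }
        out = shared_gene_frequency(mods)
        for _, row in out.iterrows():
            expected = sum(
                row.gene in mods[ct].get(row.module, set()) for ct in mods
            )
            assert row.freq == expected
        # sorted by frequency, descending
        assert (np.diff(out.freq.to_numpy()) <= 0).all()
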