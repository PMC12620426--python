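"""ssGSEA and module scoring against brute-force oracles; QC and batch
adjustment behaviour."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pvtrigger import signature as S
from pvtrigger.synthetic import generate_expression

SIG = [f"SIG{i:03d}" for i in range(30)]


def _bundle(matrix, mode="bulk", groups=None, batch=None):
    ann = pd.DataFrame(index=matrix.columns)
    ann["group"] = groups if groups is not None else "A"
    if batch is not None:
        ann["batch"] = batch
    return S.ExpressionBundle(matrix=matrix, annotation=ann, mode=mode)


class TestQcFilter:
    def _sc(self, seed=0, n=400, fail=0.05):
        return generate_expression("single_cell", n, ["monocyte", "T"], SIG,
                                   effect=0.0, seed=seed,
                                   qc_fail_fraction=fail)

    def test_planted_failures_removed_exactly(self):
        sc = self._sc()
        out = S.qc_filter_cells(sc)
        truth_fail = set(sc.annotation.index[sc.annotation["truth_qc_fail"]])
        removed = set(sc.matrix.columns) - set(out.matrix.columns)
        assert removed == truth_fail

    def test_hand_built_rule_violations(self):
        genes = ["MT-ND1", "RPS2", "HBB", "G1", "G2", "G3"]
        # c0 clean; c1 20% mito; c2 has a hemoglobin count; c3 low ribosomal
        mat = pd.DataFrame(
            {"c0": [5, 10, 0, 30, 30, 25],
             "c1": [20, 10, 0, 35, 25, 10],
             "c2": [5, 10, 1, 30, 30, 24],
             "c3": [5, 1, 0, 44, 30, 20]}, index=genes)
        bundle = _bundle(mat, mode="single_cell")
        out = S.qc_filter_cells(bundle, min_genes=3, min_cells=1)
        assert list(out.matrix.columns) == ["c0"]

    def test_idempotent(self):
        once = S.qc_filter_cells(self._sc())
        twice = S.qc_filter_cells(once)
        pd.testing.assert_frame_equal(once.matrix, twice.matrix)

    def test_all_cells_removed_raises(self):
        mat = pd.DataFrame({"c0": [10, 0, 5]}, index=["MT-ND1", "RPS2", "G1"])
        with pytest.raises(ValueError):
            S.qc_filter_cells(_bundle(mat, mode="single_cell"), min_genes=1)

    def test_bulk_mode_rejected(self):
        with pytest.raises(ValueError):
            S.qc_filter_cells(self._sc().__class__(
                matrix=pd.DataFrame({"s": [1.0]}, index=["G"]),
                annotation=pd.DataFrame(index=["s"]), mode="bulk"))


class TestBatchAdjust:
    def test_constant_shift_removed(self, rng):
        base = rng.normal(5, 1, size=(40, 20))
        shifted = base.copy()
        shifted[:, 10:] += 2.0
        mat = pd.DataFrame(shifted, index=[f"G{i}" for i in range(40)],
                           columns=[f"s{i}" for i in range(20)])
        bundle = _bundle(mat, batch=[0] * 10 + [1] * 10)
        out = S.batch_adjust(bundle)
        x = out.matrix.to_numpy()
        assert np.allclose(x[:, :10].mean(axis=1), x[:, 10:].mean(axis=1))
        # overall gene means preserved
        assert np.allclose(x.mean(axis=1), shifted.mean(axis=1))

    def test_single_batch_identity(self, rng):
        mat = pd.DataFrame(rng.normal(size=(5, 6)),
                           index=list("ABCDE"),
                           columns=[f"s{i}" for i in range(6)])
        bundle = _bundle(mat, batch=[0] * 6)
        assert S.batch_adjust(bundle).matrix.equals(mat)

    def test_biological_effect_orthogonal_to_batch_preserved(self):
        # adjustment on log2 expression (the scale batch removal is used on):
        # with the same seed, centering must restore the batch-free effect
        # to within 10%
        def log2_bundle(bundle):
            return S.ExpressionBundle(matrix=np.log2(bundle.matrix),
                                      annotation=bundle.annotation,
                                      mode=bundle.mode)

        def effect(bundle):
            x = bundle.matrix.loc[SIG].to_numpy()
            in_a = (bundle.annotation["group"] == "A").to_numpy()
            return x[:, in_a].mean() - x[:, ~in_a].mean()

        clean = generate_expression("bulk", 60, ["A", "B"], SIG, effect=1.0,
                                    seed=9, enriched_group="A", n_batches=2,
                                    batch_shift=0.0)
        batched = generate_expression("bulk", 60, ["A", "B"], SIG, effect=1.0,
                                      seed=9, enriched_group="A", n_batches=2,
                                      batch_shift=1.5)
        adjusted = S.batch_adjust(log2_bundle(batched))
        assert effect(adjusted) == pytest.approx(effect(log2_bundle(clean)),
                                                 rel=0.10)


def _ssgsea_oracle(expr: pd.Series, gene_set: list[str], alpha: float) -> float:
    """Literal running-sum definition, written independently of the
    implementation: walk genes by decreasing expression, accumulate the
    weighted in-set ECDF minus the unweighted out-of-set ECDF."""
    ranks = stats.rankdata(expr.to_numpy())
    order = np.argsort(-expr.to_numpy(), kind="stable")
    genes = list(expr.index)
    in_set = [genes[i] in gene_set for i in order]
    w = [ranks[i] ** alpha for i in order]
    denom = sum(wi for wi, s in zip(w, in_set) if s)
    n_out = sum(1 for s in in_set if not s)
    es, cin, cout = 0.0, 0.0, 0.0
    for wi, s in zip(w, in_set):
        if s:
            cin += wi / denom
        else:
            cout += 1.0 / n_out
        es += cin - cout
    return es


class TestSsgsea:
    def test_toy_matrix_equals_running_sum_oracle(self):
        mat = pd.DataFrame({"s1": [5.0, 4.0, 3.0, 2.0],
                            "s2": [1.0, 7.0, 2.0, 9.0]},
                           index=["g1", "g2", "g3", "g4"])
        res = S.ssgsea(_bundle(mat), ["g1", "g3"], alpha=0.25)
        for col in mat.columns:
            assert res.raw_scores[col] == pytest.approx(
                _ssgsea_oracle(mat[col], ["g1", "g3"], 0.25), abs=1e-12)

    def test_random_matrices_match_oracle(self, rng):
        mat = pd.DataFrame(rng.random((12, 4)),
                           index=[f"g{i}" for i in range(12)],
                           columns=[f"s{i}" for i in range(4)])
        gene_set = ["g0", "g3", "g7"]
        res = S.ssgsea(_bundle(mat), gene_set)
        for col in mat.columns:
            assert res.raw_scores[col] == pytest.approx(
                _ssgsea_oracle(mat[col], gene_set, 0.25), abs=1e-10)

    def test_top_k_set_is_extremal(self, rng):
        mat = pd.DataFrame(rng.random((10, 1)) + 1,
                           index=[f"g{i}" for i in range(10)], columns=["s"])
        top2 = list(mat["s"].nlargest(2).index)
        best = S.ssgsea(_bundle(mat), top2, normalize=False).raw_scores["s"]
        for pair in itertools.combinations(mat.index, 2):
            other = S.ssgsea(_bundle(mat), list(pair),
                             normalize=False).raw_scores["s"]
            assert other <= best + 1e-12

    def test_invariant_under_monotone_transform(self, rng):
        mat = pd.DataFrame(rng.random((30, 5)) + 0.1,
                           index=[f"g{i}" for i in range(30)],
                           columns=[f"s{i}" for i in range(5)])
        gene_set = [f"g{i}" for i in range(0, 30, 4)]
        a = S.ssgsea(_bundle(mat), gene_set).raw_scores
        b = S.ssgsea(_bundle(np.exp(3 * mat)), gene_set).raw_scores
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_empty_intersection_rejected(self, rng):
        mat = pd.DataFrame(rng.random((4, 2)), index=list("abcd"),
                           columns=["s1", "s2"])
        with pytest.raises(ValueError):
            S.ssgsea(_bundle(mat), ["zzz"])

    def test_planted_bulk_effect_raises_group_scores(self):
        b = generate_expression("bulk", 40, ["sJIA", "control"], SIG,
                                effect=1.0, seed=2, enriched_group="sJIA")
        res = S.ssgsea(b, SIG)
        means = res.scores.groupby(b.annotation["group"]).mean()
        assert means["sJIA"] > means["control"]


class TestCompareGroups:
    def test_anova_null_calibration(self, rng):
        ps = []
        for _ in range(60):
            scores = pd.Series(rng.normal(size=30),
                               index=[f"s{i}" for i in range(30)])
            groups = pd.Series(["A"] * 15 + ["B"] * 15, index=scores.index)
            ps.append(S.compare_groups(scores, groups)[1])
        # uniform p under the null: KS against U(0,1)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_shift_power(self, rng):
        hits = 0
        for _ in range(30):
            a = rng.normal(0, 1, 20)
            b = rng.normal(1.0, 1, 20)
            scores = pd.Series(np.r_[a, b],
                               index=[f"s{i}" for i in range(40)])
            groups = pd.Series(["A"] * 20 + ["B"] * 20, index=scores.index)
            hits += S.compare_groups(scores, groups)[1] < 0.05
        assert hits >= 22  # analytic power at d=1, n=20/group is ~0.87

    def test_degenerate_groups_rejected(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        groups = pd.Series(["A", "A", "B"], index=list("abc"))
        with pytest.raises(ValueError):
            S.compare_groups(scores, groups)


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        mat = pd.DataFrame(np.tile([[3.0], [3.0], [3.0], [3.0]], (1, 5)),
                           index=list("abcd"),
                           columns=[f"c{i}" for i in range(5)])
        res = S.add_module_score(_bundle(mat, mode="single_cell"), ["a", "b"],
                                 n_bins=1, n_ctrl=10, seed=0)
        assert np.allclose(res.scores.to_numpy(), 0.0)

    def test_null_effect_mean_near_zero(self):
        sc = generate_expression("single_cell", 2000, ["monocyte", "T"], SIG,
                                 effect=0.0, seed=3)
        res = S.add_module_score(sc, SIG, seed=0)
        for ct in ("monocyte", "T"):
            m = res.scores[sc.annotation["cell_type"] == ct].mean()
            assert abs(m) < 0.05

    def test_seeded_determinism(self):
        sc = generate_expression("single_cell", 200, ["monocyte", "T"], SIG,
                                 effect=1.0, seed=4)
        a = S.add_module_score(sc, SIG, seed=5).scores
        b = S.add_module_score(sc, SIG, seed=5).scores
        assert a.equals(b)

    def test_planted_signature_ranks_target_cells_highest(self):
        sc = generate_expression("single_cell", 600,
                                 ["monocyte", "T", "B"], SIG, effect=1.0,
                                 seed=6, enriched_group="monocyte")
        res = S.add_module_score(sc, SIG, seed=0)
        med = res.scores.groupby(sc.annotation["cell_type"]).median()
        assert med.idxmax() == "monocyte"


class TestCompareCelltypes:
    def test_small_sample_matches_enumeration_oracle(self, rng):
        scores = pd.Series(rng.permutation(np.arange(10, dtype=float)),
                           index=[f"c{i}" for i in range(10)])
        types = pd.Series(["X"] * 3 + ["Y"] * 7, index=scores.index)
        res = S.compare_celltypes(scores, types, alternative="greater")
        obs = scores[types == "X"].sum()
        total = 0
        ge = 0
        for combo in itertools.combinations(scores.to_numpy(), 3):
            total += 1
            ge += sum(combo) >= obs - 1e-12
        assert res.loc["X", "pvalue"] == pytest.approx(ge / total, abs=1e-9)

    def test_planted_shift_has_smallest_adjusted_p(self):
        sc = generate_expression("single_cell", 500,
                                 ["monocyte", "T", "B", "NK"], SIG,
                                 effect=1.0, seed=7,
                                 enriched_group="monocyte")
        res = S.add_module_score(sc, SIG, seed=0)
        ct = S.compare_celltypes(res.scores, sc.annotation["cell_type"])
        assert ct["padj"].idxmin() == "monocyte"

    def test_tiny_types_skipped(self, rng):
        scores = pd.Series(rng.normal(size=9),
                           index=[f"c{i}" for i in range(9)])
        types = pd.Series(["X"] * 2 + ["Y"] * 3 + ["Z"] * 4,
                          index=scores.index)
        res = S.compare_celltypes(scores, types)
        assert "X" not in res.index
        assert {"Y", "Z"} <= set(res.index)
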