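"""Inference methods against independent brute-force oracles and their
structural contracts (symmetry, zero diagonal, determinism,
permutation equivariance)."""

import numpy as np
import pytest

from grnbench import ExpressionMatrix, run_method
from grnbench.infer import MethodParams, list_methods
from grnbench.infer.corr_methods import (
    mutrank_scores,
    partial_correlation_from,
    pcit_from_correlation,
    shrunk_correlation,
    zscore_matrix,
)
from grnbench.infer.mi_methods import (
    aracne_from_mi,
    clr_from_mi,
    mrnet_from_mi,
    mrnetb_from_mi,
)

from .oracles import (
    naive_aracne,
    naive_clr,
    naive_mrnet,
    naive_mutrank,
    naive_pcit,
    naive_zscore,
)


def random_mi(g: int, seed: int) -> np.ndarray:
    r = np.random.default_rng(seed)
    m = np.abs(r.normal(size=(g, g)))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


def random_corr(g: int, n: int, seed: int) -> np.ndarray:
    r = np.random.default_rng(seed)
    return np.corrcoef(r.normal(size=(n, g)), rowvar=False)


class TestFormulaOracles:
    """Scores match independent hand evaluations of the defining formulas."""

    @pytest.mark.parametrize("seed", range(10))
    def test_clr_matches_oracle(self, seed):
        m = random_mi(3 + seed % 4, seed)
        np.testing.assert_allclose(clr_from_mi(m), naive_clr(m), atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_aracne_matches_exhaustive_triplets(self, seed):
        m = random_mi(3 + seed % 4, 100 + seed)
        np.testing.assert_allclose(
            aracne_from_mi(m), naive_aracne(m), atol=1e-10
        )

    def test_aracne_triangle_removes_weakest(self):
        m = np.array([[0, 0.9, 0.2], [0.9, 0, 0.5], [0.2, 0.5, 0]])
        out = aracne_from_mi(m)
        assert out[0, 2] == 0.0 and out[2, 0] == 0.0
        assert out[0, 1] == 0.9 and out[1, 2] == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_mutrank_matches_oracle(self, seed):
        c = random_corr(3 + seed % 4, 30, seed)
        np.testing.assert_allclose(
            mutrank_scores(c), naive_mutrank(c), atol=1e-10
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_zscore_matches_oracle(self, seed):
        r = np.random.default_rng(seed)
        values = r.normal(size=(6, 3 + seed % 4))
        np.testing.assert_allclose(
            zscore_matrix(values), naive_zscore(values), atol=1e-10
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_mrnet_matches_exhaustive_recomputation(self, seed):
        m = random_mi(4 + seed % 3, 200 + seed)
        np.testing.assert_allclose(
            mrnet_from_mi(m), naive_mrnet(m), atol=1e-10
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_pcit_matches_exhaustive_triplets(self, seed):
        c = random_corr(4 + seed % 3, 40, 300 + seed)
        np.testing.assert_allclose(
            pcit_from_correlation(c), naive_pcit(c), atol=1e-10
        )


class TestMutRank:
    def test_two_genes_best_possible_score(self):
        r = np.random.default_rng(0)
        x = r.normal(size=(20, 1))
        expr = ExpressionMatrix(np.hstack([x, 2 * x]), ["G1", "G2"])
        sm = run_method("mutrank", expr)
        assert sm.values[0, 1] == -0.5  # r12 = r21 = 1 -> s = 0.5, negated


class TestZscore:
    def test_target_at_its_mean_scores_zero(self):
        # experiment 0 knocks out gene 0; gene 1 sits exactly at its own
        # mean there (column [3, 2, 4]); the other experiments detect
        # other genes
        values = np.array([[0.0, 3.0, 1.0], [5.0, 2.0, 4.0], [3.0, 4.0, 0.5]])
        z = zscore_matrix(values)
        assert z[0, 1] == 0.0

    def test_repeat_detection_averages_rows(self):
        # gene 0 is the minimum of experiments 0 and 1
        values = np.array(
            [[-5.0, 1.0, 3.0], [-4.0, 6.0, 0.5], [10.0, 2.0, 4.0]]
        )
        z = zscore_matrix(values)
        mu = values.mean(axis=0)
        sd = values.std(axis=0)
        expected = (
            np.abs(values[0] - mu) / sd + np.abs(values[1] - mu) / sd
        ) / 2
        expected[0] = 0.0
        np.testing.assert_allclose(z[0], expected, atol=1e-12)


class TestMrnet:
    def test_two_genes_equals_mi(self):
        m = np.array([[0.0, 0.7], [0.7, 0.0]])
        np.testing.assert_allclose(mrnet_from_mi(m), m)

    def test_redundant_gene_never_selected(self):
        # gene 2 identical in MI profile to gene 1 but weaker with target 0
        m = np.array(
            [
                [0.0, 0.8, 0.6, 0.1],
                [0.8, 0.0, 0.9, 0.2],
                [0.6, 0.9, 0.0, 0.2],
                [0.1, 0.2, 0.2, 0.0],
            ]
        )
        out = mrnet_from_mi(m)
        # for target 0, gene 1 is selected first (rel 0.8); gene 2's
        # residual relevance 0.6 - 0.9 < 0, so its directed score for
        # target 0 comes only from the reverse direction
        assert out[1, 0] == 0.8


class TestMrnetb:
    def test_two_genes_matches_mrnet(self):
        m = np.array([[0.0, 0.42], [0.42, 0.0]])
        np.testing.assert_allclose(mrnetb_from_mi(m), mrnet_from_mi(m))

    @pytest.mark.parametrize("seed", range(5))
    def test_final_set_is_single_move_local_optimum(self, seed):
        """After backward elimination and sequential replacement, no
        single swap, addition or removal improves the set objective."""
        g = 5
        m = random_mi(g, 400 + seed)

        def set_objective(sel, t):
            if not sel:
                return 0.0
            rel = sum(m[j, t] for j in sel)
            if len(sel) < 2:
                return rel
            red = sum(m[a, b] for a in sel for b in sel if a != b)
            return rel - red / (len(sel) * (len(sel) - 1))

        _, sets = mrnetb_from_mi(m, return_sets=True)
        for t in range(g):
            current = set(sets[t])
            obj = set_objective(list(current), t)
            others = [j for j in range(g) if j != t and j not in current]
            moves = []
            moves += [current - {i} for i in current if len(current) > 1]
            moves += [current | {o} for o in others]
            moves += [
                (current - {i}) | {o} for i in current for o in others
            ]
            for candidate in moves:
                assert set_objective(list(candidate), t) <= obj + 1e-9


class TestGeneNet:
    def test_partial_correlation_closed_form(self):
        # 3-gene correlation with known inverse
        r = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
        p = partial_correlation_from(r)
        omega = np.linalg.inv(r)
        for i in range(3):
            for j in range(3):
                if i != j:
                    expected = -omega[i, j] / np.sqrt(omega[i, i] * omega[j, j])
                    assert abs(p[i, j] - expected) < 1e-12

    def test_independent_genes_near_zero(self):
        r = np.random.default_rng(2)
        expr = ExpressionMatrix(
            r.normal(size=(2000, 5)), [f"G{i}" for i in range(5)]
        )
        sm = run_method("genenet", expr)
        assert np.abs(sm.values).max() < 0.1

    def test_shrinkage_keeps_matrix_invertible(self):
        # fewer samples than genes: raw correlation is singular
        r = np.random.default_rng(3)
        x = r.normal(size=(5, 12))
        shrunk, lam = shrunk_correlation(x)
        assert lam > 0
        np.linalg.inv(shrunk)  # raises if singular


class TestC3net:
    @pytest.mark.parametrize("seed", range(3))
    def test_nonzero_edges_bounded_by_gene_count(self, seed):
        r = np.random.default_rng(seed)
        expr = ExpressionMatrix(
            r.normal(size=(30, 12)), [f"G{i}" for i in range(12)]
        )
        sm = run_method("c3net", expr, seed=seed)
        iu = np.triu_indices(12, 1)
        assert (sm.values[iu] > 0).sum() <= 12

    def test_dominant_pair_retained(self):
        for seed in range(10):
            r = np.random.default_rng(500 + seed)
            x = r.normal(size=(40, 4))
            x[:, 1] = x[:, 0] + 0.01 * r.normal(size=40)  # dominant pair
            expr = ExpressionMatrix(x, ["G1", "G2", "G3", "G4"])
            sm = run_method("c3net", expr, seed=seed)
            assert sm.values[0, 1] > 0

    def test_retained_scores_are_row_maxima(self):
        r = np.random.default_rng(8)
        x = r.normal(size=(50, 8))
        x[:, 1] = x[:, 0] + 0.1 * r.normal(size=50)
        x[:, 3] = x[:, 2] - 0.2 * r.normal(size=50)
        expr = ExpressionMatrix(x, [f"G{i}" for i in range(8)])
        from grnbench.infer import estimate_mi

        sm = run_method("c3net", expr, seed=1)
        m = estimate_mi(expr).values
        for i, j in zip(*np.nonzero(sm.values)):
            assert sm.values[i, j] in (m[i].max(), m[j].max())


class TestGenie3:
    def test_dominant_predictor_has_top_importance(self):
        r = np.random.default_rng(4)
        x = r.normal(size=(80, 5))
        x[:, 2] = x[:, 0] + 0.01 * r.normal(size=80)
        expr = ExpressionMatrix(x, [f"G{i}" for i in range(5)])
        sm = run_method("genie3", expr, MethodParams(genie3_trees=50), seed=0)
        assert sm.values[0, 2] == sm.values[:, 2].max()
        # a pure-noise target never reaches that importance
        assert sm.values[:, 4].max() < sm.values[0, 2]

    def test_deterministic_given_seed(self):
        r = np.random.default_rng(5)
        expr = ExpressionMatrix(
            r.normal(size=(40, 6)), [f"G{i}" for i in range(6)]
        )
        a = run_method("genie3", expr, MethodParams(genie3_trees=20), seed=3)
        b = run_method("genie3", expr, MethodParams(genie3_trees=20), seed=3)
        np.testing.assert_array_equal(a.values, b.values)


class TestRandomBaseline:
    def test_seeded_reproducibility(self):
        a = run_method("random", 30, seed=5)
        b = run_method("random", 30, seed=5)
        np.testing.assert_array_equal(a.values, b.values)
        c = run_method("random", 30, seed=6)
        assert not np.array_equal(a.values, c.values)


SYMMETRIC = ["relnet", "clr", "aracne", "c3net", "mutrank", "pcit", "genenet"]
FAST_METHODS = SYMMETRIC + ["mrnet", "mrnetb", "zscore", "random"]


class TestContracts:
    @pytest.mark.parametrize("name", FAST_METHODS)
    def test_finite_zero_diagonal_right_shape(self, name, multifactorial_source):
        expr = multifactorial_source.expr
        sm = run_method(name, expr, seed=1)
        assert sm.values.shape == (expr.n_genes, expr.n_genes)
        assert np.all(np.isfinite(sm.values))
        assert np.all(np.diag(sm.values) == 0)
        assert sm.gene_ids == expr.gene_ids

    @pytest.mark.parametrize("name", SYMMETRIC)
    def test_symmetry(self, name, multifactorial_source):
        sm = run_method(name, multifactorial_source.expr, seed=2)
        np.testing.assert_allclose(sm.values, sm.values.T, atol=1e-12)

    @pytest.mark.parametrize(
        "name", ["clr", "mrnet", "mutrank", "zscore", "pcit", "genenet",
                 "c3net", "random", "genie3"]
    )
    def test_permutation_equivariance(self, name):
        r = np.random.default_rng(6)
        g = 8
        values = r.normal(size=(25, g))
        values[:, 1] = values[:, 0] * 0.9 + 0.1 * r.normal(size=25)
        ids = [f"G{i + 1}" for i in range(g)]
        expr = ExpressionMatrix(values, ids)
        perm = np.random.default_rng(1).permutation(g)
        expr_p = ExpressionMatrix(values[:, perm], [ids[i] for i in perm])
        params = MethodParams(genie3_trees=20, c3net_permutations=50)
        a = run_method(name, expr, params, seed=9).values
        b = run_method(name, expr_p, params, seed=9).values
        np.testing.assert_allclose(a[np.ix_(perm, perm)], b, atol=1e-9)

    def test_relnet_equals_mi_off_diagonal(self, multifactorial_source):
        from grnbench.infer import estimate_mi

        sm = run_method("relnet", multifactorial_source.expr)
        m = estimate_mi(multifactorial_source.expr).values
        np.testing.assert_allclose(sm.values, m, atol=1e-12)

    def test_unknown_method_lists_registry(self):
        with pytest.raises(KeyError, match="registered methods"):
            run_method("nope", None)

    def test_registry_lists_wrapper_names(self):
        expected = {
            "aracne", "c3net", "clr", "genenet", "genie3", "mutrank",
            "mrnet", "mrnetb", "pcit", "zscore", "random",
        }
        assert expected <= set(list_methods())
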