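"""Annotation embedding, permutation testing and axis assignment."""

import numpy as np
import pytest

import axesbio as ab
from axesbio.axes import select_plateau


class TestEmbedAnnotations:
    def test_orthonormal_shortcut(self):
        rng = np.random.default_rng(0)
        B, _ = np.linalg.qr(rng.standard_normal((12, 4)))
        M = (rng.random((6, 12)) < 0.4).astype(float)
        np.testing.assert_allclose(ab.embed_annotations(M, B), M @ B,
                                   atol=1e-10)

    def test_exact_preimage_recovered(self):
        rng = np.random.default_rng(1)
        B = rng.random((10, 3)) + 0.1
        U0 = rng.random((5, 3))
        M = U0 @ B.T
        np.testing.assert_allclose(ab.embed_annotations(M, B), U0,
                                   atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        B = rng.random((5, 2)) + 0.1
        M = (rng.random((3, 5)) < 0.5).astype(float)
        U = ab.embed_annotations(M, B)
        U_ne = (np.linalg.solve(B.T @ B, B.T @ M.T)).T
        np.testing.assert_allclose(U, U_ne, atol=1e-10)

    def test_rank_deficient_basis_is_error(self):
        B = np.ones((6, 2))
        with pytest.raises(ValueError, match="rank"):
            ab.embed_annotations(np.ones((2, 6)), B)


class TestPermutationPvalues:
    def test_minimum_pvalue_is_one_over_nperm_plus_one(self):
        # a term annotating exactly the genes loading one axis beats
        # virtually every permutation on that axis
        n, d = 30, 2
        B = np.zeros((n, d))
        B[:15, 0] = 1.0
        B[15:, 1] = 1.0
        M = np.zeros((1, n))
        M[0, :15] = 1.0
        p = ab.permutation_pvalues(M, B, n_perm=200, seed=0)
        assert p.min() == pytest.approx(1 / 201)

    def test_maximum_pvalue_is_one(self):
        n = 30
        B = np.zeros((n, 2))
        B[:15, 0] = 1.0
        B[15:, 1] = 1.0
        M = np.zeros((1, n))
        M[0, :15] = 1.0
        # on the opposite axis the observed coordinate is minimal
        p = ab.permutation_pvalues(M, B, n_perm=200, seed=0)
        assert p[0, 1] == pytest.approx(1.0)

    def test_bounds_hold_everywhere(self, planted, onmtf8):
        p = ab.permutation_pvalues(planted["table"], onmtf8.B,
                                   n_perm=50, seed=3)
        assert np.all(p >= 1 / 51) and np.all(p <= 1.0)

    def test_reproducible_under_seed(self, planted, onmtf8):
        a = ab.permutation_pvalues(planted["table"], onmtf8.B,
                                   n_perm=50, seed=5)
        b = ab.permutation_pvalues(planted["table"], onmtf8.B,
                                   n_perm=50, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_two_tailed_compares_magnitudes(self):
        rng = np.random.default_rng(4)
        B = rng.standard_normal((20, 3))
        M = (rng.random((4, 20)) < 0.5).astype(float)
        p1 = ab.permutation_pvalues(M, B, n_perm=100, seed=1, tail="one")
        p2 = ab.permutation_pvalues(M, B, n_perm=100, seed=1, tail="two")
        assert p1.shape == p2.shape and not np.array_equal(p1, p2)

    def test_invalid_nperm_is_error(self):
        with pytest.raises(ValueError):
            ab.permutation_pvalues(np.ones((1, 4)), np.ones((4, 1)),
                                   n_perm=0, seed=0)

    def test_null_calibration_uniform(self, planted, onmtf8):
        """Annotations made independent of the embedding give uniform
        p-values and a controlled post-FDR discovery fraction."""
        from scipy import stats

        rng = np.random.default_rng(0)
        M = planted["table"].M[:, rng.permutation(planted["table"].n_genes)]
        p = ab.permutation_pvalues(M, onmtf8.B, n_perm=1000, seed=0)
        assert stats.kstest(p.ravel(), "uniform").pvalue > 0.01
        q = ab.fdr_adjust(p)
        assert (q <= 0.05).mean() <= 0.05


class TestFDRAdjust:
    def test_single_axis_q_equals_p(self):
        p = np.array([[0.03], [0.4]])
        np.testing.assert_allclose(ab.fdr_adjust(p), p)

    def test_identical_row_is_fixed_point(self):
        p = np.full((1, 5), 0.2)
        np.testing.assert_allclose(ab.fdr_adjust(p), 0.2)

    def test_hand_computed_step_up(self):
        p = np.array([[0.01, 0.02, 0.04, 0.8]])
        expected = np.array([[0.04, 0.04, 0.04 * 4 / 3, 0.8]])
        np.testing.assert_allclose(ab.fdr_adjust(p), expected, atol=1e-12)


class TestAssignment:
    def test_non_significant_argmax_unassigned(self):
        U = np.array([[0.9, 0.1]])
        q = np.array([[0.5, 0.01]])
        assert ab.assign_annotations_to_axes(U, q) == {}

    def test_significant_unique_maximum(self):
        U = np.array([[0.1, 0.9]])
        q = np.array([[0.9, 0.01]])
        assert ab.assign_annotations_to_axes(U, q) == {0: 1}

    def test_tied_maxima_take_lowest_axis(self):
        U = np.array([[0.5, 0.5]])
        q = np.array([[0.01, 0.01]])
        assert ab.assign_annotations_to_axes(U, q) == {0: 0}

    def test_hard_clustering_invariants(self, annotated):
        """Every assignment is the significant argmax of its row."""
        for i, j in annotated.term_to_axis.items():
            assert annotated.qvalues[i, j] <= annotated.alpha
            assert j == int(np.argmax(annotated.U[i]))
        assert np.all(annotated.pvalues >= 1 / (annotated.n_perm + 1))
        assert np.all(annotated.pvalues <= 1.0)

    def test_gene_one_hot_rows_identity(self):
        E = np.eye(4)
        assert ab.assign_genes_to_axes(E) == {0: 0, 1: 1, 2: 2, 3: 3}

    def test_gene_argmax(self):
        assert ab.assign_genes_to_axes(np.array([[0.1, 0.9]])) == {0: 1}

    def test_gene_zero_row_unassigned(self):
        out = ab.assign_genes_to_axes(np.array([[0.0, 0.0], [1.0, 0.0]]))
        assert out == {1: 0}

    def test_planted_modules_share_modal_axis(self, planted, onmtf8):
        gene_axis = ab.assign_genes_to_axes(onmtf8.E)
        labels = planted["labels"]
        ids = planted["network"].node_ids
        fracs = []
        for m in range(planted["spec"].k_modules):
            axes = [gene_axis[i] for i, g in enumerate(ids)
                    if labels[g] == m and i in gene_axis]
            modal = max(set(axes), key=axes.count)
            fracs.append(sum(a == modal for a in axes) / len(axes))
        # every module concentrates on a modal axis; the axis carrying
        # the network's global-connectivity component dilutes a couple
        assert all(f >= 0.7 for f in fracs)
        assert sum(f >= 0.9 for f in fracs) >= 4


class TestCaptureStats:
    def test_no_assignment(self):
        out = ab.capture_stats({}, d=5, t=10)
        assert out == {"pct_axes": 0.0, "pct_terms": 0.0,
                       "terms_per_axis": 0.0}

    def test_everything_assigned(self):
        m = {i: i % 4 for i in range(12)}
        out = ab.capture_stats(m, d=4, t=12)
        assert out["pct_axes"] == 100.0 and out["pct_terms"] == 100.0
        assert out["terms_per_axis"] == 3.0

    def test_matches_direct_count(self, annotated):
        cap = annotated.capture()
        axes = set(annotated.term_to_axis.values())
        assert cap["pct_axes"] == pytest.approx(100 * len(axes) / annotated.d)
        assert cap["pct_terms"] == pytest.approx(
            100 * len(annotated.term_to_axis)
            / annotated.model.table.n_terms)


class TestDimensionalityScan:
    def test_plateau_rule_examples(self):
        assert select_plateau([1, 2, 3, 4, 5], [10, 30, 49, 50, 50],
                              tol=2) == 3
        assert select_plateau([1, 2, 3], [10, 20, 30], tol=2) == 3

    def test_planted_grid_module_count_on_plateau(self, ppmi300, planted):
        """Scanning around the planted module count: d=k captures the
        bulk of the terms and lies on the selection plateau.  n_perm is
        large enough that the minimum attainable BH q at the largest d
        stays below alpha (resolution d/(n_perm+1))."""
        k = planted["spec"].k_modules
        scan = ab.dimensionality_scan(
            ppmi300, planted["table"], d_grid=[k // 2, k, 2 * k],
            n_perm=1000, seed=0, max_iter=300)
        captured = dict(zip(scan.d_grid, scan.pct_terms))
        assert captured[k] >= 80.0
        assert captured[k] >= max(scan.pct_terms) - 15.0
        assert scan.selected_d in (k // 2, k)

    def test_requires_grid(self, ppmi300, planted):
        with pytest.raises(ValueError):
            ab.dimensionality_scan(ppmi300, planted["table"], d_grid=[4])
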