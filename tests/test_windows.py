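"""Gene selection, windowing, per-window regression and lineage scanning."""

import numpy as np
import pandas as pd
import pytest

from tipscan.model import assemble_jacobian
from tipscan.windows import (
    SplicingCounts,
    WindowConfig,
    fit_window,
    instability_score,
    make_windows,
    scan_lineage,
    select_genes,
    signature_score,
    smooth_profile,
)


def counts_from(u, s, ordering=None, genes=None, branch=None):
    u = np.asarray(u, dtype=float)
    n, m = u.shape
    return SplicingCounts(
        unspliced=u,
        spliced=np.asarray(s, dtype=float),
        gene_names=genes or [f"g{i}" for i in range(m)],
        cell_ids=[f"c{i:02d}" for i in range(n)],
        ordering=np.arange(n, dtype=float) if ordering is None else np.asarray(ordering, float),
        branch_labels=branch,
    )


class TestSelectGenes:
    def test_identity_when_all_genes_kept(self, toy_counts):
        out = select_genes(toy_counts, n_genes=toy_counts.n_genes)
        assert out.gene_names == toy_counts.gene_names
        np.testing.assert_array_equal(out.spliced, toy_counts.spliced)

    def test_user_list_keeps_input_matrix_order(self, toy_counts):
        out = select_genes(toy_counts, user_list=["g3", "g1"])
        assert out.gene_names == ["g1", "g3"]
        np.testing.assert_array_equal(out.spliced[:, 1], toy_counts.spliced[:, 3])

    def test_unknown_gene_raises_listing_missing(self, toy_counts):
        with pytest.raises(KeyError, match="nope"):
            select_genes(toy_counts, user_list=["g1", "nope"])

    def test_mean_ranking_with_alphabetical_ties(self):
        # means (3, 1, 3) for names (b, a, c): the tie between b and c is
        # broken alphabetically, so n_genes=2 keeps b then c in input order.
        s = np.array([[3.0, 1.0, 3.0]] * 4)
        counts = counts_from(np.zeros_like(s), s, genes=["b", "a", "c"])
        out = select_genes(counts, n_genes=2)
        assert out.gene_names == ["b", "c"]

    def test_n_genes_too_large_raises(self, toy_counts):
        with pytest.raises(ValueError):
            select_genes(toy_counts, n_genes=99)


class TestMakeWindows:
    def test_arithmetic_examples(self):
        cfg = WindowConfig(width=20, increment=10)
        windows = make_windows(100, cfg)
        assert len(windows) == 9
        assert windows[0] == (0, 20)
        assert windows[-1] == (80, 100)
        assert make_windows(20, WindowConfig(width=20, increment=5)) == [(0, 20)]

    def test_against_brute_force_enumeration(self):
        cfg = WindowConfig(width=20, increment=7)
        windows = make_windows(57, cfg)
        brute = [(s, s + 20) for s in range(0, 57) if s % 7 == 0 and s + 20 <= 57]
        assert windows == brute
        assert len(windows) == 6

    def test_width_exceeding_cells_raises(self):
        with pytest.raises(ValueError):
            make_windows(10, WindowConfig(width=20, increment=5))


class TestFitWindow:
    def test_exact_linear_recovery(self):
        """Noiseless U = (0.5 + 0.3*S2)/beta is recovered to machine precision."""
        rng = np.random.default_rng(0)
        s2 = rng.uniform(0.1, 5.0, size=50)
        s = np.column_stack([rng.uniform(0.1, 5.0, size=50), s2])
        u = np.column_stack([0.5 + 0.3 * s2, np.ones(50)])
        fit = fit_window(u, s, ["g0", "g1"], WindowConfig(width=50, increment=1))
        assert fit.intercepts[0] == pytest.approx(0.5, abs=1e-8)
        assert fit.interaction_matrix[0, 1] == pytest.approx(0.3, abs=1e-8)
        assert fit.interaction_matrix[0, 0] == 0.0

    def test_gamma_from_proportional_counts(self):
        """U = 0.5*S with beta=1 gives the steady-state ratio gamma = 0.5."""
        rng = np.random.default_rng(1)
        s = rng.uniform(0.5, 2.0, size=(40, 2))
        fit = fit_window(0.5 * s, s, ["g0", "g1"], WindowConfig(width=40, increment=1))
        np.testing.assert_allclose(fit.gammas, 0.5, atol=1e-12)

    def test_gamma_through_origin_least_squares(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(0.5, 2.0, size=(60, 1))
        u = 0.8 * s + rng.normal(0, 0.1, size=s.shape)
        fit = fit_window(u, s, ["g0"], WindowConfig(width=60, increment=1))
        expected = float(u[:, 0] @ s[:, 0] / (s[:, 0] @ s[:, 0]))
        assert fit.gammas[0] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_spliced_gene_flagged_missing(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0.5, 2.0, size=(30, 3))
        s[:, 1] = 0.0
        u = 0.7 * s
        fit = fit_window(u, s, ["g0", "g1", "g2"], WindowConfig(width=30, increment=1))
        assert fit.missing_genes == ["g1"]
        assert assemble_jacobian(fit.drop_missing()).n_genes == 2

    def test_ridge_shrinks_toward_zero_and_matches_normal_equations(self):
        """Ridge coefficients shrink monotonically in lambda and match the
        closed-form (Xc'Xc + lambda*I)^-1 Xc'yc solution on centered data."""
        rng = np.random.default_rng(4)
        s = rng.uniform(0.1, 4.0, size=(50, 3))
        u = np.column_stack(
            [1.0 + 0.5 * s[:, 1] - 0.2 * s[:, 2], np.ones(50), np.ones(50)]
        ) + rng.normal(0, 0.05, size=(50, 3))
        norms = []
        for lam in (0.0, 1.0, 100.0, 1000.0):
            cfg = WindowConfig(width=50, increment=1, regression_kind="ridge", shrinkage=lam)
            fit = fit_window(u, s, ["g0", "g1", "g2"], cfg)
            coef = fit.interaction_matrix[0, [1, 2]]
            norms.append(np.linalg.norm(coef))
            # independent normal-equations oracle for gene 0
            x = s[:, [1, 2]]
            xc = x - x.mean(axis=0)
            yc = u[:, 0] - u[:, 0].mean()
            w = np.linalg.solve(xc.T @ xc + lam * np.eye(2), xc.T @ yc)
            np.testing.assert_allclose(coef, w, atol=1e-10)
        assert norms[0] > norms[1] > norms[2] > norms[3]

    def test_lasso_matches_penalized_objective(self):
        """The lasso fit attains a lower value of RSS + lambda*L1 than nearby
        coefficient vectors (the documented objective, not sklearn's scaling)."""
        rng = np.random.default_rng(5)
        s = rng.uniform(0.1, 4.0, size=(60, 3))
        u = np.column_stack([0.5 + 0.8 * s[:, 1], np.ones(60), np.ones(60)])
        lam = 5.0
        cfg = WindowConfig(width=60, increment=1, regression_kind="lasso", shrinkage=lam)
        fit = fit_window(u, s, ["g0", "g1", "g2"], cfg)

        def objective(a0, coef):
            resid = a0 + s[:, [1, 2]] @ coef - u[:, 0]
            return resid @ resid + lam * np.abs(coef).sum()

        a0, coef = fit.intercepts[0], fit.interaction_matrix[0, [1, 2]]
        base = objective(a0, coef)
        rng2 = np.random.default_rng(6)
        for _ in range(50):
            assert base <= objective(a0, coef + rng2.normal(0, 0.01, 2)) + 1e-9


class TestScanLineage:
    def test_stationary_stable_process_all_windows_stable(self):
        """Cells fluctuating around a stable fixed point yield negative
        largest eigenvalues in every window."""
        rng = np.random.default_rng(7)
        n, m = 400, 3
        s = 2.0 + rng.normal(0, 0.2, size=(n, m))
        # steady state of dU/dt = 1.2 - beta*U (no interactions), gamma ~ 0.6
        u = 0.6 * s + rng.normal(0, 0.05, size=(n, m))
        counts = counts_from(np.clip(u, 0, None), np.clip(s, 0.01, None))
        prof = scan_lineage(counts, WindowConfig(width=100, increment=50, seed=0))
        assert (prof.summary["largest_real_mean"] < 0).all()

    def test_full_subsample_has_zero_iteration_spread(self, toy_counts):
        cfg = WindowConfig(width=20, increment=10, subsample_fraction=1.0, seed=0)
        prof = scan_lineage(toy_counts, cfg)
        for col in ("largest_real_std", "n_positive_std", "frac_positive_std"):
            np.testing.assert_allclose(prof.summary[col].dropna(), 0.0, atol=1e-15)

    def test_deterministic_given_seed(self, toy_counts):
        cfg = WindowConfig(width=20, increment=5, seed=123)
        p1 = scan_lineage(toy_counts, cfg)
        p2 = scan_lineage(toy_counts, cfg)
        pd.testing.assert_frame_equal(p1.iterations, p2.iterations)
        pd.testing.assert_frame_equal(p1.summary, p2.summary)

    def test_window_count_and_positions_sorted(self, toy_counts):
        cfg = WindowConfig(width=10, increment=4, seed=0)
        prof = scan_lineage(toy_counts, cfg)
        assert prof.n_windows == (toy_counts.n_cells - 10) // 4 + 1
        assert (np.diff(prof.window_positions) > 0).all()


class TestSmoothProfile:
    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(smooth_profile(np.full(20, 3.3), 2.0), 3.3)

    def test_sigma_zero_is_identity(self):
        x = np.arange(10, dtype=float)
        np.testing.assert_array_equal(smooth_profile(x, 0.0), x)

    def test_impulse_response_sums_to_one(self):
        x = np.zeros(41)
        x[20] = 1.0
        out = smooth_profile(x, 3.0)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert out[20] == out.max()

    def test_negative_sigma_raises(self):
        with pytest.raises(ValueError):
            smooth_profile(np.ones(5), -1.0)


class TestInstabilityScore:
    def _profile(self, counts, largest_reals, positions):
        """Hand-built profile stub with given per-window means."""
        from tipscan.windows import LineageStabilityProfile

        positions = np.asarray(positions, dtype=float)
        k = len(largest_reals)
        summary = pd.DataFrame(
            {"position": positions, "largest_real_mean": largest_reals},
            index=pd.RangeIndex(k, name="window"),
        )
        return LineageStabilityProfile(
            window_positions=positions,
            window_ranges=[(0, 1)] * k,
            iterations=pd.DataFrame(),
            summary=summary,
            fits=[None] * k,
            mean_expression=np.zeros((k, counts.n_genes)),
            gene_names=counts.gene_names,
            config=WindowConfig(width=2, increment=1),
        )

    def test_all_stable_clamped_to_zero(self, toy_counts):
        prof = self._profile(toy_counts, [-0.5, -0.2, -0.4], [5.0, 15.0, 25.0])
        score = instability_score(prof, toy_counts, sigma=0.0)
        np.testing.assert_array_equal(score.global_score, 0.0)

    def test_single_unstable_window_maps_to_nearest_cells(self):
        counts = counts_from(np.ones((10, 2)), np.ones((10, 2)), ordering=np.arange(10.0))
        prof = self._profile(counts, [-0.1, 0.3, -0.2], [1.0, 4.5, 8.0])
        score = instability_score(prof, counts, sigma=0.0)
        # cells with ordering 3..6 are nearest the unstable window at 4.5
        expected = np.where((counts.ordering >= 3) & (counts.ordering <= 6), 0.3, 0.0)
        np.testing.assert_allclose(score.global_score, expected)

    def test_branch_scores_take_maximum(self):
        branch = np.array(["a"] * 5 + ["b"] * 5)
        counts = counts_from(
            np.ones((10, 2)), np.ones((10, 2)), ordering=np.arange(10.0), branch=branch
        )
        prof_a = self._profile(counts, [0.2], [2.0])
        prof_b = self._profile(counts, [-1.0], [7.0])
        score = instability_score({"a": prof_a, "b": prof_b}, counts, sigma=0.0)
        np.testing.assert_allclose(score.global_score[:5], 0.2)
        np.testing.assert_allclose(score.global_score[5:], 0.0)

    def test_cells_outside_branches_score_zero_with_warning(self):
        branch = np.array(["a"] * 5 + ["orphan"] * 5)
        counts = counts_from(
            np.ones((10, 2)), np.ones((10, 2)), ordering=np.arange(10.0), branch=branch
        )
        prof_a = self._profile(counts, [0.5], [2.0])
        with pytest.warns(UserWarning, match="no branch"):
            score = instability_score({"a": prof_a}, counts, sigma=0.0)
        np.testing.assert_allclose(score.global_score[5:], 0.0)


class TestSignatureScore:
    def test_single_gene_is_scaled_expression(self, toy_counts):
        score = signature_score(toy_counts, ["g2"])
        col = toy_counts.spliced[:, 2]
        expected = (col - col.min()) / (col.max() - col.min())
        np.testing.assert_allclose(score, expected)

    def test_constant_gene_contributes_zero(self):
        s = np.column_stack([np.full(4, 2.0), np.array([0.0, 1.0, 2.0, 3.0])])
        counts = counts_from(np.zeros_like(s), s, genes=["flat", "var"])
        score = signature_score(counts, ["flat", "var"])
        np.testing.assert_allclose(score, np.array([0.0, 1 / 3, 2 / 3, 1.0]) / 2)

    def test_two_gene_hand_computation(self):
        s = np.array([[0.0, 4.0], [1.0, 2.0], [2.0, 0.0], [4.0, 4.0]])
        counts = counts_from(np.zeros_like(s), s, genes=["a", "b"])
        score = signature_score(counts, ["a", "b"])
        expected = np.array([(0 + 1) / 2, (0.25 + 0.5) / 2, (0.5 + 0) / 2, (1 + 1) / 2])
        np.testing.assert_allclose(score, expected)

    def test_empty_intersection_raises(self, toy_counts):
        with pytest.raises(KeyError):
            signature_score(toy_counts, ["absent"])
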