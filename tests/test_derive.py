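import numpy as np
import pytest

from ssmpca import (
    Volume,
    BinaryMask,
    SubjectProfileMatrix,
    build_profiles,
    double_center,
    run_pca,
    select_components,
    fit_logistic_combination,
    build_pattern,
    derive_pattern,
    save_pattern,
    load_pattern,
)
from ssmpca.derive import PCABasis


def _profiles(values, labels, state="log"):
    values = np.asarray(values, dtype=float)
    mask = BinaryMask(np.ones((1, 1, values.shape[1]), dtype=bool))
    ids = [f"s{i}" for i in range(values.shape[0])]
    return SubjectProfileMatrix(values, state, ids, list(labels), mask)


class TestBuildProfiles:
    def test_closed_form_log(self):
        data = np.array([[[1.0, np.e, np.e**2]]])
        v = Volume(data, id="s0")
        mask = BinaryMask(np.ones((1, 1, 3), dtype=bool))
        p = build_profiles([v], mask, ["control"])
        np.testing.assert_allclose(p.values[0], [0.0, 1.0, 2.0], atol=1e-12)

    def test_scaling_shifts_row_by_log_c(self, rng):
        data = rng.uniform(1, 10, size=(1, 1, 5))
        mask = BinaryMask(np.ones((1, 1, 5), dtype=bool))
        p1 = build_profiles([Volume(data)], mask, ["control"])
        p2 = build_profiles([Volume(3.0 * data)], mask, ["control"])
        np.testing.assert_allclose(p2.values - p1.values, np.log(3.0), rtol=1e-12)

    def test_matches_elementwise_log_oracle(self, rng):
        data = rng.uniform(0.5, 50, size=(4, 4, 4))
        mask = BinaryMask(rng.random((4, 4, 4)) > 0.3)
        p = build_profiles([Volume(data)], mask, ["control"])
        np.testing.assert_array_equal(p.values[0], np.log(data.ravel()[mask.voxel_order]))

    def test_nonpositive_voxel_names_subject(self):
        data = np.ones((1, 1, 3))
        data[0, 0, 1] = 0.0
        mask = BinaryMask(np.ones((1, 1, 3), dtype=bool))
        with pytest.raises(ValueError, match="bad_scan"):
            build_profiles([Volume(data, id="bad_scan")], mask, ["control"])


class TestDoubleCenter:
    def test_hand_computed_2x2(self):
        p = _profiles([[1.0, 3.0], [2.0, 2.0]], ["control", "patient"])
        res, offset = double_center(p)
        np.testing.assert_allclose(offset, [-1.0, 1.0])
        np.testing.assert_allclose(res.values, [[0.0, 0.0], [1.0, -1.0]])

    def test_defining_properties(self, rng):
        vals = rng.normal(size=(8, 30))
        labels = ["control"] * 3 + ["patient"] * 5
        res, _ = double_center(_profiles(vals, labels))
        np.testing.assert_allclose(res.values.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(res.values[:3].mean(axis=0), 0.0, atol=1e-10)

    def test_matches_naive_two_step_oracle(self, rng):
        vals = rng.normal(size=(10, 50))
        labels = ["control"] * 4 + ["patient"] * 6
        res, offset = double_center(_profiles(vals, labels))
        step1 = vals - vals.mean(axis=1)[:, None]
        ctrl_mean = step1[:4].mean(axis=0)
        np.testing.assert_allclose(res.values, step1 - ctrl_mean, atol=1e-12)
        np.testing.assert_allclose(offset, ctrl_mean, atol=1e-12)

    def test_requires_controls(self, rng):
        p = _profiles(rng.normal(size=(3, 5)), ["patient"] * 3)
        with pytest.raises(ValueError, match="control"):
            double_center(p)


class TestRunPCA:
    def test_rank_one_residual(self):
        base = np.array([1.0, -1.0, 0.5, -0.5])
        base -= base.mean()
        vals = np.outer([1.0, -1.0, 2.0], base)
        # make the control column mean zero by adding a compensating row set
        p = _profiles(vals, ["control", "control", "patient"], state="residual")
        p.values -= p.values[:2].mean(axis=0)
        p.values -= p.values.mean(axis=1, keepdims=True)
        b = run_pca(p)
        assert b.variance_fractions[0] == pytest.approx(1.0)

    def test_orthonormality_and_reconstruction(self, rng):
        vals = rng.normal(size=(6, 40))
        labels = ["control"] * 3 + ["patient"] * 3
        res, _ = double_center(_profiles(vals, labels))
        b = run_pca(res)
        k = b.voxel_components.shape[0]
        np.testing.assert_allclose(
            b.voxel_components @ b.voxel_components.T, np.eye(k), atol=1e-8
        )
        recon = b.subject_scores @ b.voxel_components
        np.testing.assert_allclose(recon, res.values, atol=1e-8)

    def test_matches_dense_svd_oracle(self, rng):
        vals = rng.normal(size=(6, 40))
        labels = ["control"] * 3 + ["patient"] * 3
        res, _ = double_center(_profiles(vals, labels))
        b = run_pca(res)
        _, s, vt = np.linalg.svd(res.values, full_matrices=False)
        nz = s > 1e-8 * s[0]
        expected_var = s[nz] ** 2 / (s**2).sum()
        np.testing.assert_allclose(b.variance_fractions, expected_var, atol=1e-10)
        for i in range(nz.sum()):
            dot = abs(b.voxel_components[i] @ vt[i])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_subject_space_equals_voxel_space_pca(self, rng):
        """Gram-matrix route agrees with voxel-space covariance eigenvectors
        at 20 subjects x 500 voxels, after sign alignment."""
        vals = rng.normal(size=(20, 500))
        labels = ["control"] * 10 + ["patient"] * 10
        res, _ = double_center(_profiles(vals, labels))
        b = run_pca(res)
        cov = res.values.T @ res.values  # voxel-space scatter
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        k = b.voxel_components.shape[0]
        np.testing.assert_allclose(
            b.variance_fractions, evals[:k] / evals[evals > 1e-10].sum(), atol=1e-8
        )
        for i in range(k):
            assert abs(b.voxel_components[i] @ evecs[:, i]) == pytest.approx(1.0, abs=1e-8)

    def test_rank_zero_rejected(self):
        p = _profiles(np.zeros((4, 10)), ["control"] * 2 + ["patient"] * 2,
                      state="residual")
        with pytest.raises(ValueError, match="rank 0"):
            run_pca(p)


class TestSelectComponents:
    def _basis(self, fractions):
        k = len(fractions)
        return PCABasis(np.eye(k), np.eye(k), np.asarray(fractions))

    def test_prefix_rule(self):
        b = self._basis([0.30, 0.15, 0.10, 0.25, 0.20])
        assert select_components(b, 0.50) == [0, 1, 2]

    def test_first_pc_sufficient(self):
        b = self._basis([0.60, 0.40])
        assert select_components(b, 0.50) == [0]

    def test_prefix_reaches_target(self, small_pattern):
        _, basis = small_pattern
        sel = select_components(basis, 0.5)
        assert sel == list(range(len(sel)))
        assert basis.variance_fractions[sel].sum() >= 0.5
        if len(sel) > 1:
            assert basis.variance_fractions[sel[:-1]].sum() < 0.5


class TestLogisticCombination:
    def test_dominant_predictor_selected(self, rng):
        n = 30
        labels = ["control"] * 15 + ["patient"] * 15
        scores = rng.normal(size=(n, 5))
        scores[:, 2] = np.where(np.arange(n) < 15, -2.0, 2.0) + 0.1 * rng.normal(size=n)
        b = PCABasis(np.eye(5), scores, np.full(5, 0.2))
        selected, _ = fit_logistic_combination(b, [0, 1, 2, 3, 4], labels)
        assert 2 in selected

    def test_matches_bruteforce_aic_enumeration(self, rng):
        """AIC-best subset equals an independent enumeration with plain
        maximum-likelihood fits on well-separated (non-degenerate) scores."""
        import itertools
        import statsmodels.api as sm

        n = 40
        labels = ["control"] * 20 + ["patient"] * 20
        y = np.array([0.0] * 20 + [1.0] * 20)
        scores = rng.normal(size=(n, 6))
        scores[:, 1] += 0.8 * y
        scores[:, 4] += 0.6 * y
        b = PCABasis(np.eye(6), scores, np.full(6, 1 / 6))
        selected, coefs = fit_logistic_combination(b, list(range(6)), labels,
                                                   max_subset_size=4)
        best = None
        for size in range(1, 5):
            for subset in itertools.combinations(range(6), size):
                x = sm.add_constant(scores[:, list(subset)])
                aic = sm.Logit(y, x).fit(disp=0).aic
                if best is None or aic < best[0]:
                    best = (aic, list(subset))
        assert selected == best[1]

    def test_noncontiguous_subsets_possible(self, rng):
        n = 24
        labels = ["control"] * 12 + ["patient"] * 12
        y = np.array([0.0] * 12 + [1.0] * 12)
        scores = rng.normal(size=(n, 4))
        scores[:, 0] += 1.2 * y
        scores[:, 3] += 1.2 * y
        b = PCABasis(np.eye(4), scores, np.full(4, 0.25))
        selected, _ = fit_logistic_combination(b, [0, 1, 2, 3], labels)
        assert selected == sorted(selected)  # indices, not necessarily contiguous

    def test_requires_both_groups(self, rng):
        b = PCABasis(np.eye(3), rng.normal(size=(6, 3)), np.full(3, 1 / 3))
        with pytest.raises(ValueError, match="groups"):
            fit_logistic_combination(b, [0], ["control"] * 6)


class TestBuildPattern:
    def _toy_basis(self, rng):
        vals = rng.normal(size=(8, 25))
        labels = ["control"] * 4 + ["patient"] * 4
        res, offset = double_center(_profiles(vals, labels))
        return run_pca(res), offset, res

    def test_single_pc_identity(self, rng):
        b, offset, res = self._toy_basis(rng)
        p = build_pattern(b, [0], np.array([1.0]), offset, res.mask)
        np.testing.assert_allclose(p.weights, b.voxel_components[0], atol=1e-12)
        assert p.norm_factor == pytest.approx(1.0)

    def test_negating_coefficients_negates_weights(self, rng):
        b, offset, res = self._toy_basis(rng)
        p1 = build_pattern(b, [0, 1], np.array([0.7, -0.3]), offset, res.mask)
        p2 = build_pattern(b, [0, 1], np.array([-0.7, 0.3]), offset, res.mask)
        np.testing.assert_allclose(p1.weights, -p2.weights, atol=1e-12)

    def test_weighted_sum_oracle(self, rng):
        b, offset, res = self._toy_basis(rng)
        coefs = np.array([0.5, 1.5, -2.0])
        p = build_pattern(b, [0, 1, 2], coefs, offset, res.mask)
        expected = np.zeros(res.mask.n_voxels)
        for c, i in zip(coefs, [0, 1, 2]):
            expected += c * b.voxel_components[i]
        expected /= np.linalg.norm(expected)
        np.testing.assert_allclose(p.weights, expected, atol=1e-12)
        assert np.linalg.norm(p.weights) == pytest.approx(1.0)


class TestGlobalScalingInvariance:
    def test_scaling_one_subject_leaves_everything_unchanged(self, derivation, small_mask):
        scans, labels = derivation
        scaled = [v.scaled(4.2) if i == 3 else v for i, v in enumerate(scans)]
        res1, _ = double_center(build_profiles(scans, small_mask, labels))
        res2, _ = double_center(build_profiles(scaled, small_mask, labels))
        np.testing.assert_allclose(res1.values, res2.values, atol=1e-10)
        b1, b2 = run_pca(res1), run_pca(res2)
        np.testing.assert_allclose(b1.subject_scores, b2.subject_scores, atol=1e-8)


class TestPatternPersistence:
    def test_save_load_roundtrip(self, small_pattern, tmp_path):
        pattern, _ = small_pattern
        save_pattern(pattern, tmp_path / "pat")
        back = load_pattern(tmp_path / "pat")
        np.testing.assert_allclose(back.weights, pattern.weights, atol=1e-6)
        np.testing.assert_allclose(back.reference_offset, pattern.reference_offset,
                                   atol=1e-6)
        assert back.selected_pcs == pattern.selected_pcs
        assert back.control_score_mean == pytest.approx(pattern.control_score_mean)


class TestParameterRecovery:
    def test_recovers_embedded_component_small_scale(self, small_cfg, small_cohort,
                                                     derivation, small_mask, small_pattern):
        """The derived pattern correlates strongly with the embedded
        disease component on the analysis mask."""
        _, gt = small_cohort
        pattern, _ = small_pattern
        flat_w = np.zeros(int(np.prod(small_mask.shape)))
        flat_w[small_mask.voxel_order] = pattern.weights
        flat_c = np.zeros(int(np.prod(gt.shell_mask.shape)))
        flat_c[gt.shell_mask.voxel_order] = gt.components[0]
        common = np.flatnonzero((small_mask.data & gt.shell_mask.data).ravel())
        r = np.corrcoef(flat_w[common], flat_c[common])[0, 1]
        assert abs(r) >= 0.8
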