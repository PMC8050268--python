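"""Trial-space PCA tests: explained variance, orientation, PC modules."""

import numpy as np
import pytest

import pitchsynergy as ps
from pitchsynergy.exceptions import DegenerateInputError
from pitchsynergy.trialspace import fisher_ratio


def _labels(n_per=10):
    return np.repeat([50, 80, 100], n_per)


class TestPCATrialComponents:
    def test_two_informative_columns_explain_everything(self):
        rng = np.random.default_rng(0)
        U = np.zeros((12, 4))
        U[:, 0] = rng.random(12)
        U[:, 2] = rng.random(12)
        pca = ps.pca_trial_components(U)
        assert pca.explained_fraction_2d == pytest.approx(1.0)

    def test_isotropic_columns_explain_two_over_r(self):
        """Equal variance, zero correlation: the top 2 of R directions
        hold exactly 2/R of the variance."""
        from scipy.linalg import hadamard
        H = hadamard(8).astype(float)
        U = 1.0 + H[:, 1:6]  # 5 mean-zero orthogonal columns, shifted >= 0
        pca = ps.pca_trial_components(U)
        assert pca.explained_fraction_2d == pytest.approx(2.0 / 5)

    def test_scores_are_uncentered_projections(self):
        rng = np.random.default_rng(1)
        U = rng.random((9, 3))
        pca = ps.pca_trial_components(U)
        np.testing.assert_allclose(pca.scores, U @ pca.loadings, atol=1e-12)
        np.testing.assert_allclose(
            pca.loadings.T @ pca.loadings, np.eye(2), atol=1e-10)

    def test_rank_deficient_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            ps.pca_trial_components(np.random.default_rng(0).random((9, 1)))
        with pytest.raises(DegenerateInputError):
            ps.pca_trial_components(np.ones((9, 3)))  # zero covariance


class TestOrientAndAssignRoles:
    def _pca(self, scores):
        return ps.TrialPCA(
            loadings=np.eye(2), scores=np.asarray(scores, dtype=float),
            explained_fraction_2d=1.0, eigenvalues=np.array([2.0, 1.0]))

    def test_already_ordered_scores_unflipped(self):
        s = np.column_stack([np.repeat([0.0, 1.0, 2.0], 10),
                             np.repeat([0.0, 0.5, 1.5], 10)])
        out = ps.orient_and_assign_roles(self._pca(s), _labels())
        np.testing.assert_array_equal(out.scores, s)

    def test_orientation_is_involutive(self):
        s = np.column_stack([np.repeat([0.0, 1.0, 2.0], 10),
                             np.repeat([0.0, 0.5, 1.5], 10)])
        out1 = ps.orient_and_assign_roles(self._pca(s), _labels())
        out2 = ps.orient_and_assign_roles(self._pca(-s), _labels())
        np.testing.assert_allclose(out1.scores, out2.scores, atol=1e-12)

    def test_flip_targets_correct_groups(self):
        """PC1 flips on 100 vs 50 means; PC2 flips on 100 vs 80 means."""
        s = np.column_stack([np.repeat([2.0, 1.0, 0.0], 10),   # 100 < 50
                             np.repeat([0.0, 1.5, 0.5], 10)])  # 100 < 80
        out = ps.orient_and_assign_roles(self._pca(s), _labels())
        assert out.scores[:, 0].max() <= 0  # flipped
        assert out.scores[:, 1].max() <= 0

    def test_gate_on_second_axis_triggers_swap(self):
        """When the gate contrast lives on the smaller-variance axis the
        roles swap (the atypical-subject case)."""
        rng = np.random.default_rng(2)
        lab = _labels()
        fine_axis = np.where(lab == 100, 3.0, 0.0) + rng.normal(0, 1.2, 30)
        gate_axis = np.where(lab == 50, 0.0, 1.0) + rng.normal(0, 0.05, 30)
        out = ps.orient_and_assign_roles(
            self._pca(np.column_stack([fine_axis, gate_axis])), lab)
        assert out.swap_applied
        assert out.role == {"gate": 2, "fine": 1}

    def test_missing_effort_group_rejected(self):
        s = np.random.default_rng(0).random((20, 2))
        with pytest.raises(ValueError):
            ps.orient_and_assign_roles(self._pca(s), np.repeat([50, 80], 10))

    def test_fisher_ratio_separation(self):
        x = np.concatenate([np.zeros(10), np.ones(20)])
        assert fisher_ratio(x, x == 0) == np.inf
        x2 = x + np.linspace(-0.1, 0.1, 30)
        assert fisher_ratio(x2, x == 0) > 50


class TestPCAssociatedModules:
    def test_single_component_returns_factors(self, ref_fit):
        pca = ps.TrialPCA(
            loadings=np.column_stack([np.eye(ref_fit.rank)[:, 0],
                                      np.eye(ref_fit.rank)[:, 1]]),
            scores=np.zeros((30, 2)), explained_fraction_2d=1.0,
            eigenvalues=np.ones(2))
        mod = ps.pc_associated_modules(ref_fit, pca, 1)
        np.testing.assert_allclose(mod.spatial_pc, ref_fit.spatial[:, 0],
                                   atol=1e-12)
        np.testing.assert_allclose(mod.temporal_pc, ref_fit.temporal[:, 0],
                                   atol=1e-12)

    def test_modules_unit_norm_and_may_be_negative(self, ref_fit):
        pca = ps.pca_trial_components(ref_fit.trial)
        for which in (1, 2):
            mod = ps.pc_associated_modules(ref_fit, pca, which)
            assert np.linalg.norm(mod.spatial_pc) == pytest.approx(1.0)
            assert np.linalg.norm(mod.temporal_pc) == pytest.approx(1.0)

    def test_gate_module_finds_planted_muscles(self, recovery_suite):
        """Dominant muscles of the planted gate component are among the
        largest-magnitude entries of the gate PC spatial module."""
        hits = 0
        for run in recovery_suite[:10]:
            mod = ps.pc_associated_modules(
                run.model, run.pca, run.pca.role["gate"])
            planted = set(run.gt.dominant_muscles[run.gt.gate_component])
            k = len(planted)
            top = set(np.argsort(np.abs(mod.spatial_pc))[-k:])
            if len(top & planted) >= k - 1:
                hits += 1
        assert hits >= 8

    def test_rank_mismatch_rejected(self, ref_fit):
        pca = ps.pca_trial_components(
            np.random.default_rng(0).random((30, ref_fit.rank + 1)))
        with pytest.raises(ValueError):
            ps.pc_associated_modules(ref_fit, pca, 1)


class TestOrientModulesCrossSubject:
    def _mod(self, spatial, temporal):
        return ps.PCModule(spatial_pc=np.asarray(spatial, dtype=float),
                           temporal_pc=np.asarray(temporal, dtype=float),
                           which_pc=1)

    def test_all_positive_unchanged(self):
        m = self._mod(np.full(18, 0.2), np.full(150, 0.08))
        out = ps.orient_modules_cross_subject(m)
        assert not out.sign_flipped

    def test_both_negative_flipped(self):
        m = self._mod(-np.full(18, 0.2), -np.full(150, 0.08))
        out = ps.orient_modules_cross_subject(m)
        assert out.sign_flipped
        assert np.all(out.spatial_pc > 0) and np.all(out.temporal_pc > 0)

    def test_insignificant_negative_mean_unchanged(self):
        """High-variance entries straddling 0: mean < 0 but t-test not
        significant, so no flip."""
        rng = np.random.default_rng(3)
        spatial = rng.normal(-0.01, 1.0, 18)
        spatial -= spatial.mean() - (-0.01)  # pin a slightly negative mean
        m = self._mod(spatial, -np.full(150, 0.08))
        out = ps.orient_modules_cross_subject(m)
        assert not out.sign_flipped

    def test_flip_preserves_magnitudes(self, ref_fit):
        pca = ps.pca_trial_components(ref_fit.trial)
        mod = ps.pc_associated_modules(ref_fit, pca, 1)
        flipped = ps.PCModule(-mod.spatial_pc, -mod.temporal_pc, 1)
        out = ps.orient_modules_cross_subject(flipped)
        np.testing.assert_allclose(np.abs(out.spatial_pc),
                                   np.abs(mod.spatial_pc), atol=1e-12)
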