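"""Nonnegative CP solver tests: exactness, monotonicity, rank selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pitchsynergy as ps
from pitchsynergy.exceptions import ConstraintError, DegenerateInputError


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestFitNTF:
    def test_noiseless_rank1_recovery_is_exact(self):
        """A pure outer product is recovered to cosine >= 0.999 and
        lambda within 0.1%."""
        a = _unit([0.9, 0.1, 0.4, 0.2])
        b = _unit([0.2, 0.8, 0.3, 0.1, 0.6])
        c = _unit([0.5, 0.5, 0.7])
        lam = 3.7
        X = lam * np.einsum("i,j,k->ijk", a, b, c)
        m = ps.fit_ntf(X, 1, restarts=3, seed=0, tol=1e-12, max_iter=2000)
        assert m.lambdas[0] == pytest.approx(lam, rel=1e-3)
        for got, want in ((m.spatial[:, 0], a), (m.temporal[:, 0], b),
                          (m.trial[:, 0], c)):
            assert float(got @ want) >= 0.999

    def test_all_zero_tensor_gives_zero_model(self):
        m = ps.fit_ntf(np.zeros((2, 2, 2)), 1, restarts=2, seed=0)
        assert m.lambdas.sum() == 0.0
        assert m.diagnostics.objective == 0.0

    def test_negative_tensor_rejected(self):
        X = np.ones((2, 2, 2))
        X[0, 0, 0] = -1
        with pytest.raises(ConstraintError):
            ps.fit_ntf(X, 1)

    def test_invalid_rank_rejected(self, ref_tensor):
        with pytest.raises(ValueError):
            ps.fit_ntf(ref_tensor, 0)

    def test_objective_nonincreasing_every_sweep(self, ref_fit):
        h = ref_fit.diagnostics.objective_history
        assert np.all(np.diff(h) <= 1e-9 * max(h[0], 1.0))

    def test_factors_unit_norm_sorted_by_lambda(self, ref_fit):
        for F in (ref_fit.spatial, ref_fit.temporal, ref_fit.trial):
            assert np.all(F >= 0)
            np.testing.assert_allclose(np.linalg.norm(F, axis=0), 1.0,
                                       atol=1e-9)
        assert np.all(np.diff(ref_fit.lambdas) <= 1e-12)


class TestReconstruct:
    def test_single_basis_component(self):
        m = ps.CPModel(
            spatial=np.array([[1.0], [0.0]]),
            temporal=np.array([[0.0], [1.0], [0.0]]),
            trial=np.array([[0.0], [1.0]]),
            lambdas=np.array([2.0]))
        X = ps.reconstruct(m)
        assert X[0, 1, 1] == 2.0
        assert X.sum() == 2.0

    def test_noiseless_fit_reconstructs_input(self):
        """Rank-1 noiseless input is reproduced to 1e-6 relative error;
        rank-2 to 1e-3 (multiplicative updates slow to a sublinear crawl
        near a multi-component optimum)."""
        cfg1 = ps.ScenarioConfig(true_rank=1, noise_sd=0.0)
        gt1 = ps.generate_ground_truth(cfg1, seed=4)
        X1 = ps.render_tensor(gt1, seed=4).X
        m1 = ps.fit_ntf(X1, 1, restarts=2, seed=0, tol=1e-14, max_iter=3000)
        assert (np.linalg.norm(X1 - ps.reconstruct(m1))
                / np.linalg.norm(X1)) < 1e-6

        cfg2 = ps.ScenarioConfig(true_rank=2, noise_sd=0.0)
        gt2 = ps.generate_ground_truth(cfg2, seed=4)
        X2 = ps.render_tensor(gt2, seed=4).X
        m2 = ps.fit_ntf(X2, 2, restarts=2, seed=0, tol=1e-12, max_iter=2000)
        assert (np.linalg.norm(X2 - ps.reconstruct(m2))
                / np.linalg.norm(X2)) < 1e-3

    def test_normalization_is_noop_on_reconstruction(self, ref_fit):
        """All scale lives in lambda: rescaling columns and absorbing the
        norms reproduces the same reconstruction exactly."""
        X1 = ps.reconstruct(ref_fit)
        scaled = ps.CPModel(
            spatial=ref_fit.spatial * ref_fit.lambdas,
            temporal=ref_fit.temporal,
            trial=ref_fit.trial,
            lambdas=np.ones(ref_fit.rank))
        np.testing.assert_allclose(X1, ps.reconstruct(scaled), rtol=1e-12)


class TestUncenteredR2:
    def test_hand_worked_values(self):
        X = np.array([1.0, 2.0]).reshape(1, 1, 2)
        assert ps.uncentered_r2(X, X) == 1.0
        assert ps.uncentered_r2(X, np.zeros_like(X)) == 0.0
        Xhat = np.array([1.0, 1.0]).reshape(1, 1, 2)
        assert ps.uncentered_r2(X, Xhat) == pytest.approx(0.8)

    def test_all_zero_input_undefined(self):
        with pytest.raises(DegenerateInputError):
            ps.uncentered_r2(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((3, 4, 2))
        Xhat = rng.random((3, 4, 2)) * rng.choice([0.5, 1.0, 2.0])
        assert 0.0 <= ps.uncentered_r2(X, Xhat) <= 1.0


class TestSelectRank:
    def test_noiseless_rank3_reaches_one(self):
        cfg = ps.ScenarioConfig(true_rank=3, noise_sd=0.0)
        gt = ps.generate_ground_truth(cfg, seed=6)
        X = ps.render_tensor(gt, seed=6).X
        scan = ps.select_rank(X, threshold=0.80, r_max=5, restarts=2,
                              seed=0, tol=1e-10, max_iter=1500)
        assert scan.reached and scan.selected_rank <= 3
        full = ps.select_rank(X, threshold=0.80, r_max=3, restarts=2,
                              seed=0, tol=1e-10, max_iter=1500,
                              full_scan=True)
        assert full.r2[-1] == pytest.approx(1.0, abs=1e-6)

    def test_unreachable_threshold_flags_not_reached(self, ref_tensor):
        scan = ps.select_rank(ref_tensor, threshold=0.999999, r_max=3,
                              restarts=1, seed=0, tol=1e-6, max_iter=100)
        assert not scan.reached
        assert scan.selected_rank == 3

    def test_selected_rank_nondecreasing_in_threshold(self, ref_tensor):
        scan = ps.select_rank(ref_tensor, threshold=0.90, r_max=8,
                              restarts=2, seed=0, tol=1e-6, max_iter=300)
        picks = [scan.select(th)[0] for th in (0.70, 0.75, 0.80, 0.85, 0.90)]
        assert all(a <= b for a, b in zip(picks, picks[1:]))


class TestParameterCount:
    @pytest.mark.parametrize("layout,expected", [
        ("cp", 1584),
        ("nnmf_shared_spatial", 36144),
        ("nnmf_per_trial", 40320),
    ])
    def test_reference_design_counts(self, layout, expected):
        assert ps.parameter_count(18, 150, 30, 8, layout) == expected

    def test_minimal_cp(self):
        assert ps.parameter_count(1, 1, 1, 1, "cp") == 3

    def test_unknown_layout_rejected(self):
        with pytest.raises(ValueError):
            ps.parameter_count(2, 2, 2, 1, "tucker")
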