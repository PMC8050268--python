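"""Generator tests: planted structure, determinism, raw-EMG round trip."""

import numpy as np
import pytest

import pitchsynergy as ps
from pitchsynergy.exceptions import InvalidConfigError
from pitchsynergy.preprocess import assemble_tensor, preprocess_recording


class TestGroundTruth:
    def test_reference_scenario_shapes_and_norms(self, ref_gt, ref_tensor):
        """18 muscles x 150 frames x 30 trials; factor columns unit norm."""
        assert ref_tensor.X.shape == (18, 150, 30)
        assert np.sum(ref_gt.effort_labels == 50) == 10
        for F in (ref_gt.spatial_true, ref_gt.temporal_true,
                  ref_gt.trial_true):
            assert np.all(F >= 0)
            np.testing.assert_allclose(np.linalg.norm(F, axis=0), 1.0,
                                       atol=1e-12)

    def test_gate_and_fine_gain_ordering(self, ref_gt):
        """Planted per-effort block means: gate g50 < g80 ~ g100 and
        fine g80 < g100, read back from the generated trial factor."""
        u = ref_gt.trial_true
        lab = ref_gt.effort_labels
        gate = u[:, ref_gt.gate_component]
        means = {e: gate[lab == e].mean() for e in (50, 80, 100)}
        assert means[50] < means[80] <= means[100] * 1.1
        fine = u[:, ref_gt.fine_component]
        assert fine[lab == 80].mean() < fine[lab == 100].mean()

    def test_rank1_equal_gains_has_no_effort_effect(self):
        cfg = ps.ScenarioConfig(true_rank=1, gains=np.ones((3, 1)),
                                jitter_sd=0.05)
        gt = ps.generate_ground_truth(cfg, seed=7)
        u = gt.trial_true[:, 0]
        block = [u[gt.effort_labels == e].mean() for e in (50, 80, 100)]
        assert np.ptp(block) < 0.2 * np.mean(block)

    def test_seeded_determinism(self):
        a = ps.generate_ground_truth(seed=5)
        b = ps.generate_ground_truth(seed=5)
        np.testing.assert_array_equal(a.spatial_true, b.spatial_true)
        np.testing.assert_array_equal(
            ps.render_tensor(a, seed=9).X, ps.render_tensor(b, seed=9).X)

    @pytest.mark.parametrize("bad", [
        dict(true_rank=0), dict(n_muscles=0), dict(noise_sd=-1.0),
        dict(gains=-np.ones((3, 4))), dict(jitter_sd=-0.1),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(InvalidConfigError):
            ps.generate_ground_truth(ps.ScenarioConfig(**bad), seed=0)


class TestRenderTensor:
    def test_noiseless_rank1_is_exact_outer_product(self):
        cfg = ps.ScenarioConfig(true_rank=1, noise_sd=0.0)
        gt = ps.generate_ground_truth(cfg, seed=1)
        X = ps.render_tensor(gt, seed=1).X
        expected = gt.lambda_true[0] * np.einsum(
            "i,j,k->ijk", gt.spatial_true[:, 0], gt.temporal_true[:, 0],
            gt.trial_true[:, 0])
        np.testing.assert_allclose(X, expected, atol=1e-12)

    def test_noiseless_rank3_reconstruction_r2_is_one(self):
        cfg = ps.ScenarioConfig(true_rank=3, noise_sd=0.0)
        gt = ps.generate_ground_truth(cfg, seed=2)
        X = ps.render_tensor(gt, seed=2).X
        assert ps.uncentered_r2(X, gt.clean_tensor()) == pytest.approx(1.0)

    def test_rendered_values_nonnegative_with_noise(self, ref_tensor):
        assert np.all(ref_tensor.X >= 0)

    def test_noise_calibration_hits_explainable_variance(
            self, ref_gt, ref_tensor):
        """The clean tensor explains ~0.85 of the rendered variance."""
        r2 = ps.uncentered_r2(ref_tensor.X, ref_gt.clean_tensor())
        assert r2 == pytest.approx(0.85, abs=0.02)

    def test_selected_rank_near_truth(self, ref_tensor, ref_gt):
        """At the 0.80 criterion the scan stops within 2 of the true rank."""
        scan = ps.select_rank(ref_tensor, threshold=0.80, r_max=8,
                              restarts=2, seed=0, tol=1e-6, max_iter=300)
        assert scan.reached
        assert scan.selected_rank <= ref_gt.true_rank + 2


class TestRenderRawEMG:
    def test_zero_envelope_preprocesses_to_zero(self):
        cfg = ps.ScenarioConfig(true_rank=1, noise_sd=0.0,
                                component_weights=np.array([0.0]))
        gt = ps.generate_ground_truth(cfg, seed=0)
        rec = ps.render_raw_emg(gt, seed=0)[0]
        env = preprocess_recording(rec)
        assert np.allclose(env, 0.0, atol=1e-8)

    def test_constant_envelope_ripple_below_ten_percent(self):
        """A flat unit envelope survives rectify + low-pass with < 10%
        relative ripple in the recovered envelope."""
        rng = np.random.default_rng(0)
        from pitchsynergy.synth import _bandlimited_carrier
        n = 4000
        carrier = _bandlimited_carrier(n, 2000.0, rng)
        rec = ps.RawEMGRecording(
            samples=np.column_stack([0.3 + carrier, 0.3 + carrier]),
            sampling_rate=2000.0, channel_labels=("a", "b"),
            release_index=3500, effort=50, ball_speed=100.0)
        env = preprocess_recording(rec)[0]
        core = env[10:-5]  # drop window-edge frames
        assert np.std(core) / np.mean(core) < 0.10

    def test_round_trip_recovers_planted_envelopes(self):
        """preprocess(render_raw_emg(gt)) ~ render_tensor(gt): r > 0.9 per
        channel on the noiseless scenario; under calibrated noise the
        out-of-band envelope noise is unrecoverable by a 10 Hz filter, so
        the bound applies to signal-dominated (dominant-muscle) channels."""
        for seed in (3, 4):
            cfg = ps.ScenarioConfig(noise_sd=0.0)
            gt = ps.generate_ground_truth(cfg, seed=seed)
            recs = ps.render_raw_emg(gt, seed=seed)
            envs = [preprocess_recording(r) for r in recs]
            got = assemble_tensor(envs, [r.effort for r in recs])
            ref = ps.render_tensor(gt, seed=seed)
            rs = [np.corrcoef(got.X[i].ravel(), ref.X[i].ravel())[0, 1]
                  for i in range(gt.n_muscles)]
            assert min(rs) > 0.9

        gt = ps.generate_ground_truth(seed=3)
        recs = ps.render_raw_emg(gt, seed=3)
        envs = [preprocess_recording(r) for r in recs]
        got = assemble_tensor(envs, [r.effort for r in recs])
        ref = ps.render_tensor(gt, seed=3)
        dom = sorted({m for comp in gt.dominant_muscles for m in comp})
        rs = [np.corrcoef(got.X[i].ravel(), ref.X[i].ravel())[0, 1]
              for i in dom]
        assert min(rs) > 0.85

    def test_release_index_allows_full_window(self, ref_gt):
        rec = ps.render_raw_emg(ref_gt, seed=0)[0]
        assert rec.release_index >= 1490
        assert rec.release_index < rec.samples.shape[0]

    def test_carrier_fs_must_be_reasonable(self, ref_gt):
        with pytest.raises(InvalidConfigError):
            ps.render_raw_emg(ref_gt, carrier_fs=100.0, seed=0)
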