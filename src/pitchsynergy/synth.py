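"""Synthetic EMG generator with planted low-rank structure and effort effects.

Every downstream stage of the pipeline (preprocessing, nonnegative CP
decomposition, trial-space PCA, effort classification) is exercised here
against a known ground truth: a nonnegative rank-``R*`` tensor whose

* spatial factors are sparse muscle-weight vectors (a few dominant
  muscles per component over a small background),
* temporal factors are phase-locked Gaussian bursts inside the 750 ms
  window ending at ball release, and
* trial factors carry per-effort mean gains with multiplicative
  lognormal jitter.

The default scenario mirrors the experimental design it emulates:
18 channels, 150 frames at 200 Hz, 30 trials in three 10-trial effort
blocks (50/80/100% subjective effort), rank 4 with one "gate" component
(50% effort recruited less than 80% ~ 100%) and one "fine" component
(100% recruited more than 80%). Additive Gaussian noise is calibrated so
that a rank-``R*`` model explains about 85% of the uncentered variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CHANNEL_ORDER, EFFORT_LEVELS, EMGTensor, RawEMGRecording
from .exceptions import InvalidConfigError

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "generate_ground_truth",
    "render_tensor",
    "render_raw_emg",
]


@dataclass
class ScenarioConfig:
    """Parameters of the planted-structure scenario.

    The defaults define the reference scenario used throughout the test
    suite; they are study conditions, not tuning knobs.
    """

    n_muscles: int = 18
    n_frames: int = 150
    n_trials_per_effort: int = 10
    true_rank: int = 4
    #: per-effort mean gains, shape (3, R*): rows follow EFFORT_LEVELS.
    #: None selects the reference pattern (see ``_default_gains``).
    gains: np.ndarray | None = None
    #: relative component weights before global amplitude scaling.
    component_weights: np.ndarray | None = None
    burst_centers: np.ndarray | None = None
    burst_widths: np.ndarray | None = None
    #: dominant muscles per component; None -> 2-4 drawn without
    #: replacement so components occupy distinct muscle groups.
    dominant_muscles: list[tuple[int, ...]] | None = None
    background_weight: float = 0.06
    #: sigma of the mean-one lognormal trial jitter on gains.
    jitter_sd: float = 0.15
    #: additive noise sd; None calibrates to ``target_explained``.
    noise_sd: float | None = None
    #: uncentered variance fraction a rank-R* model should explain when
    #: noise_sd is calibrated automatically.
    target_explained: float = 0.85
    #: per-effort ball-speed (mean, sd) in km/h: large 50->80 step,
    #: small 80->100 step.
    ball_speed_params: tuple[tuple[float, float], ...] = (
        (105.0, 2.0), (125.0, 2.0), (130.0, 2.0))


def _default_gains(rank: int) -> np.ndarray:
    """Reference per-effort gain pattern: component 1 gates 50% vs
    {80, 100}%, component 2 distinguishes 80% from 100%, the rest are
    effort-independent baselines."""
    g = np.ones((3, rank))
    if rank >= 2:
        g[:, 1] = (0.5, 1.5, 1.6)   # gate: g50 < g80 ~ g100
    if rank >= 3:
        g[:, 2] = (0.8, 1.0, 1.8)   # fine: g80 < g100
    if rank >= 4:
        g[:, 3] = (1.1, 1.0, 1.0)
    return g


@dataclass
class GroundTruth:
    """A fully specified generative model for one synthetic subject.

    Factor columns are unit Euclidean norm; all scale lives in
    ``lambda_true``. ``gains[e, r]`` stores the per-effort mean gain the
    trial column was built from, before normalization.
    """

    n_muscles: int
    n_frames: int
    n_trials_per_effort: int
    true_rank: int
    spatial_true: np.ndarray
    temporal_true: np.ndarray
    trial_true: np.ndarray
    lambda_true: np.ndarray
    gains: np.ndarray
    noise_sd: float
    effort_labels: np.ndarray
    ball_speed_params: tuple[tuple[float, float], ...]
    jitter_sd: float
    burst_centers: np.ndarray
    burst_widths: np.ndarray
    dominant_muscles: list[tuple[int, ...]]
    seed: int
    gate_component: int | None = None
    fine_component: int | None = None
    muscle_labels: tuple[str, ...] = field(default=CHANNEL_ORDER)

    @property
    def n_trials(self) -> int:
        return 3 * self.n_trials_per_effort

    def clean_tensor(self) -> np.ndarray:
        """Noiseless multilinear expansion sum_r lambda_r s_r o t_r o u_r."""
        return np.einsum(
            "r,ir,jr,kr->ijk",
            self.lambda_true, self.spatial_true, self.temporal_true,
            self.trial_true,
        )


def _unit_columns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(mat, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    return mat / safe, norms


def generate_ground_truth(
    config: ScenarioConfig | None = None, seed: int = 0
) -> GroundTruth:
    """Draw a :class:`GroundTruth` for the configured scenario.

    Deterministic given ``seed``. Temporal columns are discretized
    Gaussian bumps renormalized to unit norm; spatial columns place unit
    weight on a few dominant muscles over a small uniform background;
    trial columns are per-effort gains with lognormal jitter, column-
    normalized with the scale absorbed into ``lambda_true``. Amplitudes
    are scaled globally so the noiseless tensor peaks at 1, matching the
    range of min-max normalized envelopes.
    """
    cfg = config if config is not None else ScenarioConfig()
    S, T, R = cfg.n_muscles, cfg.n_frames, cfg.true_rank
    npe = cfg.n_trials_per_effort
    if S < 1 or T < 1 or npe < 1 or R < 1:
        raise InvalidConfigError("dimensions and rank must be positive")
    if cfg.noise_sd is not None and cfg.noise_sd < 0:
        raise InvalidConfigError("noise_sd must be nonnegative")
    gains = np.asarray(cfg.gains if cfg.gains is not None else _default_gains(R),
                       dtype=float)
    if gains.shape != (3, R):
        raise InvalidConfigError(f"gains must have shape (3, {R})")
    if np.any(gains < 0):
        raise InvalidConfigError("gains must be nonnegative")
    if cfg.jitter_sd < 0:
        raise InvalidConfigError("jitter_sd must be nonnegative")

    rng = np.random.default_rng(seed)

    # --- temporal factors: Gaussian bursts spread over the window
    if cfg.burst_centers is not None:
        centers = np.asarray(cfg.burst_centers, dtype=float)
    elif R == 1:
        centers = np.array([0.6 * T])
    else:
        centers = np.linspace(0.25 * T, 0.92 * T, R)
    if np.any(centers < 0) or np.any(centers > T):
        raise InvalidConfigError("burst centers must lie within the frame window")
    widths = (np.asarray(cfg.burst_widths, dtype=float)
              if cfg.burst_widths is not None else np.full(R, T / 15.0))
    frames = np.arange(T, dtype=float)[:, None]
    temporal = np.exp(-0.5 * ((frames - centers[None, :]) / widths[None, :]) ** 2)
    temporal, _ = _unit_columns(temporal)

    # --- spatial factors: 2-4 dominant muscles each, distinct across
    # components when possible, over a small background
    if cfg.dominant_muscles is not None:
        dominant = [tuple(d) for d in cfg.dominant_muscles]
    else:
        order = rng.permutation(S)
        dominant, pos = [], 0
        for _ in range(R):
            k = int(rng.integers(2, 5))
            if pos + k > S:  # recycle when components outnumber muscles
                order = rng.permutation(S)
                pos = 0
            dominant.append(tuple(int(m) for m in order[pos:pos + k]))
            pos += k
    spatial = np.full((S, R), cfg.background_weight)
    spatial *= rng.uniform(0.5, 1.5, size=(S, R))
    for r, muscles in enumerate(dominant):
        spatial[list(muscles), r] = rng.uniform(0.8, 1.2, size=len(muscles))
    spatial, _ = _unit_columns(spatial)

    # --- trial factors: per-effort gains x mean-one lognormal jitter
    K = 3 * npe
    effort_labels = np.repeat(EFFORT_LEVELS, npe)
    u_raw = np.empty((K, R))
    for e_idx in range(3):
        block = slice(e_idx * npe, (e_idx + 1) * npe)
        jit = rng.lognormal(-0.5 * cfg.jitter_sd ** 2, cfg.jitter_sd, (npe, R))
        u_raw[block] = gains[e_idx][None, :] * jit
    trial, u_norms = _unit_columns(u_raw)

    weights = (np.asarray(cfg.component_weights, dtype=float)
               if cfg.component_weights is not None
               else np.linspace(1.0, 0.7, R))
    if np.any(weights < 0):
        raise InvalidConfigError("component weights must be nonnegative")
    lam = weights * u_norms
    clean = np.einsum("r,ir,jr,kr->ijk", lam, spatial, temporal, trial)
    peak = clean.max()
    if peak > 0:
        lam = lam / peak

    # --- noise calibrated so a rank-R* model explains ~target_explained
    if cfg.noise_sd is not None:
        noise_sd = float(cfg.noise_sd)
    else:
        ve = cfg.target_explained
        if not 0 < ve < 1:
            raise InvalidConfigError("target_explained must be in (0, 1)")
        scaled = clean / peak if peak > 0 else clean
        noise_sd = _calibrate_noise_sd(scaled, ve)

    gate = 1 if (cfg.gains is None and R >= 2) else None
    fine = 2 if (cfg.gains is None and R >= 3) else None
    labels = (CHANNEL_ORDER if S == len(CHANNEL_ORDER)
              else tuple(f"M{i + 1}" for i in range(S)))
    return GroundTruth(
        n_muscles=S, n_frames=T, n_trials_per_effort=npe, true_rank=R,
        spatial_true=spatial, temporal_true=temporal, trial_true=trial,
        lambda_true=lam, gains=gains, noise_sd=noise_sd,
        effort_labels=effort_labels, ball_speed_params=cfg.ball_speed_params,
        jitter_sd=cfg.jitter_sd, burst_centers=centers, burst_widths=widths,
        dominant_muscles=dominant, seed=seed,
        gate_component=gate, fine_component=fine, muscle_labels=labels,
    )


def _calibrate_noise_sd(clean: np.ndarray, target: float) -> float:
    """Noise sd at which the clean tensor explains ``target`` of the
    uncentered variance of the rendered (noisy, zero-clipped) tensor.

    Uses the closed-form moments of ``max(0, m + eps)`` for Gaussian
    ``eps``: with a = m/sigma,

        E[(clip - m)^2] = sigma^2 (Phi(a) - a phi(a)) + m^2 Phi(-a)
        E[clip^2]       = (m^2 + sigma^2) Phi(a) + m sigma phi(a)

    and solves 1 - sum E[(clip-m)^2] / sum E[clip^2] = target by
    bisection. Deterministic; no sampling involved.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    m = clean.ravel()
    mean_sq = float(np.mean(m * m))
    if mean_sq == 0.0:
        return 0.0

    def explained(sigma: float) -> float:
        a = m / sigma
        phi, Phi = norm.pdf(a), norm.cdf(a)
        resid = sigma ** 2 * (Phi - a * phi) + m ** 2 * (1.0 - Phi)
        power = (m ** 2 + sigma ** 2) * Phi + m * sigma * phi
        return 1.0 - resid.sum() / power.sum()

    # un-clipped first guess, then bracket and refine
    sigma0 = np.sqrt((1 - target) / target * mean_sq)
    lo, hi = sigma0, sigma0
    while explained(hi) > target:
        hi *= 2.0
    while explained(lo) < target:
        lo /= 2.0
    return float(brentq(lambda s: explained(s) - target, lo, hi, xtol=1e-10))


def _simulate_ball_speeds(gt: GroundTruth, rng: np.random.Generator) -> np.ndarray:
    speeds = np.empty(gt.n_trials)
    for e_idx, (mean, sd) in enumerate(gt.ball_speed_params):
        block = slice(e_idx * gt.n_trials_per_effort,
                      (e_idx + 1) * gt.n_trials_per_effort)
        speeds[block] = rng.normal(mean, sd, gt.n_trials_per_effort)
    return speeds


def render_tensor(gt: GroundTruth, seed: int = 0) -> EMGTensor:
    """Render the noisy nonnegative tensor X = max(0, sum of rank-1 terms + eps).

    ``eps ~ Normal(0, noise_sd)`` i.i.d. per entry; deterministic given
    ``seed``. Ball speeds are simulated from the per-effort parameters.
    """
    rng = np.random.default_rng(seed)
    X = gt.clean_tensor()
    if gt.noise_sd > 0:
        X = X + rng.normal(0.0, gt.noise_sd, X.shape)
    X = np.clip(X, 0.0, None)
    return EMGTensor(
        X=X,
        muscle_labels=gt.muscle_labels,
        effort_labels=gt.effort_labels,
        ball_speeds=_simulate_ball_speeds(gt, rng),
        subject_id=f"synthetic-{gt.seed}",
    )


def _bandlimited_carrier(
    n: int, fs: float, rng: np.random.Generator,
    band: tuple[float, float] = (20.0, 500.0),
) -> np.ndarray:
    """Zero-mean Gaussian carrier band-limited to ``band``, scaled so the
    expected rectified value E|c| is 1 (rectify + low-pass then recovers
    the modulating envelope)."""
    from scipy import signal

    high = min(band[1], 0.45 * fs)
    taps = signal.firwin(129, [band[0], high], pass_zero=False, fs=fs)
    c = signal.lfilter(taps, 1.0, rng.standard_normal(n + 256))[256:]
    return c / np.mean(np.abs(c))


def render_raw_emg(
    gt: GroundTruth,
    carrier_fs: float = 2000.0,
    seed: int = 0,
    dc_offset: float = 0.3,
    lead_samples: int = 2000,
    trail_samples: int = 500,
) -> list[RawEMGRecording]:
    """Render per-trial raw EMG whose envelope is the planted activity.

    Each channel is ``dc_offset + envelope(t) * carrier(t)`` with an
    independent band-limited zero-mean Gaussian carrier, so the standard
    chain (offset removal, full-wave rectification, 10 Hz low-pass,
    resampling) recovers the envelope. The envelope is the same noisy
    realization :func:`render_tensor` yields for this seed, linearly
    upsampled from the frame rate to ``carrier_fs``; release is the last
    envelope sample, recorded in the trial metadata.
    """
    if carrier_fs < 400:
        raise InvalidConfigError("carrier_fs must be at least 400 Hz")
    tensor = render_tensor(gt, seed=seed)
    rng = np.random.default_rng(np.random.default_rng(seed).integers(2 ** 31))
    frame_fs = tensor.frame_rate_hz
    up = carrier_fs / frame_fs
    T = gt.n_frames
    n_env = int(round((T - 1) * up)) + 1
    env_t = np.arange(n_env) / up
    release = lead_samples + n_env - 1
    n_total = lead_samples + n_env + trail_samples

    recordings = []
    for k in range(gt.n_trials):
        chans = np.empty((n_total, gt.n_muscles))
        for i in range(gt.n_muscles):
            env = np.interp(env_t, np.arange(T, dtype=float), tensor.X[i, :, k])
            full = np.concatenate([
                np.full(lead_samples, env[0]), env, np.full(trail_samples, env[-1])])
            carrier = _bandlimited_carrier(n_total, carrier_fs, rng)
            chans[:, i] = dc_offset + full * carrier
        recordings.append(RawEMGRecording(
            samples=chans,
            sampling_rate=carrier_fs,
            channel_labels=gt.muscle_labels,
            release_index=release,
            effort=int(gt.effort_labels[k]),
            ball_speed=float(tensor.ball_speeds[k]),
            subject_id=tensor.subject_id,
            trial_id=k + 1,
        ))
    return recordings
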