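"""Shared fixtures: reference-scenario tensors, fits and recovery suites.

Heavy objects (CP fits over many seeds) are session-scoped so the
recovery, trial-space and acceptance tests share one computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import pitchsynergy as ps

#: fit settings used by the simulation suites: a handful of restarts and
#: a looser tolerance keep the full suite fast while recovering planted
#: factors to cosine > 0.99 on the reference scenario.
FIT_KW = dict(restarts=3, tol=1e-7, max_iter=400)
SCAN_KW = dict(restarts=2, tol=1e-6, max_iter=300)

RECOVERY_SEEDS = tuple(range(20))


@pytest.fixture(scope="session")
def ref_gt() -> ps.GroundTruth:
    return ps.generate_ground_truth(seed=11)


@pytest.fixture(scope="session")
def ref_tensor(ref_gt) -> ps.EMGTensor:
    return ps.render_tensor(ref_gt, seed=11)


@pytest.fixture(scope="session")
def ref_fit(ref_tensor) -> ps.CPModel:
    return ps.fit_ntf(ref_tensor, 4, seed=0, **FIT_KW)


@dataclass
class RecoveryRun:
    seed: int
    gt: ps.GroundTruth
    tensor: ps.EMGTensor
    model: ps.CPModel
    match: ps.MatchResult
    pca: "ps.TrialPCA"


@pytest.fixture(scope="session")
def recovery_suite() -> list[RecoveryRun]:
    """Reference-scenario fits over 20 seeds, shared by the factor-
    recovery and trial-space recovery checks."""
    runs = []
    for seed in RECOVERY_SEEDS:
        gt = ps.generate_ground_truth(seed=seed)
        tensor = ps.render_tensor(gt, seed=seed)
        model = ps.fit_ntf(tensor, gt.true_rank, seed=seed, **FIT_KW)
        pca = ps.orient_and_assign_roles(
            ps.pca_trial_components(model.trial), tensor.effort_labels)
        runs.append(RecoveryRun(
            seed=seed, gt=gt, tensor=tensor, model=model,
            match=ps.match_components(model, gt), pca=pca))
    return runs


@pytest.fixture(scope="session")
def separated_clusters():
    """Three well-separated score clusters mirroring the gate-then-fine
    geometry: the gate axis splits 50 from {80, 100}, the fine axis
    splits 80 from 100. 20 trials per class so leaf-size selection has
    headroom."""
    rng = np.random.default_rng(42)
    n = 20
    labels = np.repeat([50, 80, 100], n)
    centers = {50: (0.0, 0.5), 80: (2.0, 0.0), 100: (2.0, 2.0)}
    scores = np.vstack([
        rng.normal(centers[e], 0.12, size=(n, 2)) for e in (50, 80, 100)])
    return scores, labels
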