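"""Match fitted CP components to planted ground-truth components.

CP components are identifiable only up to permutation (signs are fixed
by nonnegativity, scale by the unit-norm convention), so recovery is
scored after a Hungarian assignment maximizing the summed cosine
similarity of the spatial columns; the same permutation is then applied
to the temporal and trial modes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .decompose import CPModel
from .synth import GroundTruth

__all__ = ["MatchResult", "cosine_matrix", "match_components"]


@dataclass
class MatchResult:
    permutation: np.ndarray          # fitted column matched to truth column r
    spatial_cosines: np.ndarray
    temporal_cosines: np.ndarray
    trial_cosines: np.ndarray

    def mean_cosine(self, mode: str) -> float:
        return float(getattr(self, f"{mode}_cosines").mean())


def cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between columns of ``A`` and ``B``."""
    na = np.linalg.norm(A, axis=0, keepdims=True)
    nb = np.linalg.norm(B, axis=0, keepdims=True)
    return (A / np.where(na > 0, na, 1)).T @ (B / np.where(nb > 0, nb, 1))


def match_components(model: CPModel, gt: GroundTruth) -> MatchResult:
    """Hungarian match on spatial factors; cosines reported per mode."""
    C = cosine_matrix(gt.spatial_true, model.spatial)
    rows, cols = linear_sum_assignment(-C)
    perm = cols[np.argsort(rows)]
    idx = np.arange(perm.size)
    return MatchResult(
        permutation=perm,
        spatial_cosines=C[idx, perm],
        temporal_cosines=cosine_matrix(
            gt.temporal_true, model.temporal)[idx, perm],
        trial_cosines=cosine_matrix(gt.trial_true, model.trial)[idx, perm],
    )
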