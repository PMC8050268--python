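"""Low-dimensional structure of the trial components: gate and fine axes.

The R trial-factor columns of a fitted CP model vary across trials and
effort blocks. PCA over the trial components finds the two directions
carrying most of that variance. With three effort levels two roles recur:

* a **gate** axis separating 50% effort from {80%, 100%} — assigned to
  the PC maximizing the Fisher ratio between those groups, and
* a **fine** axis distinguishing 80% from 100% effort.

In most subjects the gate is PC1; when the gate effect loads on the
second variance direction the roles swap (``swap_applied``).

Loadings are the top-2 eigenvectors of the sample covariance of the
trial factor matrix (columns centered over trials, divisor K - 1);
scores are projections of the *uncentered* trial components, so the
score clouds keep their nonnegative offset. Sign conventions are pure
orientation: PC1 flips so that the 100%-effort group mean exceeds the
50% one, PC2 so that 100% exceeds 80%.

PC-associated spatiotemporal modules blend the CP factor columns with
the PC loadings, renormalized to unit norm; because loadings may be
negative, these modules can carry negative entries even though the CP
factors are nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .decompose import CPModel
from .exceptions import DegenerateInputError

__all__ = [
    "TrialPCA",
    "PCModule",
    "pca_trial_components",
    "orient_and_assign_roles",
    "pc_associated_modules",
    "orient_modules_cross_subject",
    "fisher_ratio",
]


@dataclass
class TrialPCA:
    """Two retained principal directions of the trial components."""

    loadings: np.ndarray          # (R, 2), unit-norm orthogonal columns
    scores: np.ndarray            # (K, 2), projections of uncentered u_r
    explained_fraction_2d: float  # (e1 + e2) / trace of the covariance
    eigenvalues: np.ndarray       # (2,)
    role: dict[str, int] | None = None   # {"gate": 1|2, "fine": 1|2}
    swap_applied: bool = False
    effort_labels: np.ndarray | None = None

    @property
    def loadings_1(self) -> np.ndarray:
        return self.loadings[:, 0]

    @property
    def loadings_2(self) -> np.ndarray:
        return self.loadings[:, 1]

    @property
    def scores_1(self) -> np.ndarray:
        return self.scores[:, 0]

    @property
    def scores_2(self) -> np.ndarray:
        return self.scores[:, 1]

    def role_scores(self, role: str) -> np.ndarray:
        """Score vector of the PC assigned to ``role`` ('gate' or 'fine')."""
        if self.role is None:
            raise ValueError("roles not assigned; run orient_and_assign_roles")
        return self.scores[:, self.role[role] - 1]


@dataclass
class PCModule:
    """Signed, unit-norm PC-associated spatial and temporal module."""

    spatial_pc: np.ndarray
    temporal_pc: np.ndarray
    which_pc: int
    sign_flipped: bool = False


def pca_trial_components(U: np.ndarray) -> TrialPCA:
    """Top-2 PCA of the trial factor matrix ``U`` (K trials x R components).

    Eigenvectors come from the centered sample covariance; scores are
    ``U @ loadings`` without centering.
    """
    U = np.asarray(U, dtype=float)
    K, R = U.shape
    if R < 2:
        raise DegenerateInputError("at least 2 trial components are required")
    if K < 3:
        raise DegenerateInputError("at least 3 trials are required")
    cov = np.cov(U, rowvar=False, ddof=1)
    total = float(np.trace(cov))
    if total <= 0:
        raise DegenerateInputError("trial components have zero variance")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:2]
    evals, evecs = evals[order], evecs[:, order]
    # deterministic pre-orientation: largest-|loading| entry positive
    for m in range(2):
        j = np.argmax(np.abs(evecs[:, m]))
        if evecs[j, m] < 0:
            evecs[:, m] = -evecs[:, m]
    return TrialPCA(
        loadings=evecs,
        scores=U @ evecs,
        explained_fraction_2d=float(evals.sum() / total),
        eigenvalues=evals,
    )


def fisher_ratio(values: np.ndarray, mask_a: np.ndarray) -> float:
    """Between-group separation (mu_a - mu_b)^2 over pooled within variance."""
    a, b = values[mask_a], values[~mask_a]
    na, nb = a.size, b.size
    pooled = (((na - 1) * a.var(ddof=1) if na > 1 else 0.0)
              + ((nb - 1) * b.var(ddof=1) if nb > 1 else 0.0))
    pooled /= max(na + nb - 2, 1)
    diff2 = (a.mean() - b.mean()) ** 2
    if pooled == 0.0:
        return np.inf if diff2 > 0 else 0.0
    return float(diff2 / pooled)


def orient_and_assign_roles(pca: TrialPCA, effort_labels: np.ndarray) -> TrialPCA:
    """Fix score signs against the effort blocks and label gate/fine axes.

    PC1 is flipped so mean score(100%) > mean score(50%); PC2 so that
    mean score(100%) > mean score(80%). The gate role goes to the PC with
    the larger Fisher ratio between {50} and {80, 100}; ``swap_applied``
    records the atypical case where that is PC2.
    """
    effort_labels = np.asarray(effort_labels, dtype=int)
    groups = {e: effort_labels == e for e in (50, 80, 100)}
    for e, mask in groups.items():
        if not mask.any():
            raise ValueError(f"effort group {e} is missing")
    loadings = pca.loadings.copy()
    scores = pca.scores.copy()
    for m, (hi, lo) in enumerate([(100, 50), (100, 80)]):
        if scores[groups[hi], m].mean() < scores[groups[lo], m].mean():
            scores[:, m] = -scores[:, m]
            loadings[:, m] = -loadings[:, m]
    low_vs_high = groups[50]
    ratios = [fisher_ratio(scores[:, m], low_vs_high) for m in range(2)]
    gate = 1 if ratios[0] >= ratios[1] else 2
    return replace(
        pca,
        loadings=loadings,
        scores=scores,
        role={"gate": gate, "fine": 3 - gate},
        swap_applied=gate == 2,
        effort_labels=effort_labels,
    )


def pc_associated_modules(model: CPModel, pca: TrialPCA, which_pc: int) -> PCModule:
    """Blend CP spatial/temporal factors with one PC's loadings.

    Returns unit-norm ``sum_r v_{m r} s_r`` and ``sum_r v_{m r} t_r``;
    entries may be negative.
    """
    if which_pc not in (1, 2):
        raise ValueError("which_pc must be 1 or 2")
    if model.rank != pca.loadings.shape[0]:
        raise ValueError("model rank and PCA loadings length differ")
    v = pca.loadings[:, which_pc - 1]
    spatial = model.spatial @ v
    temporal = model.temporal @ v
    ns, nt = np.linalg.norm(spatial), np.linalg.norm(temporal)
    if ns == 0 or nt == 0:
        raise DegenerateInputError("PC-weighted module sum has zero norm")
    return PCModule(spatial_pc=spatial / ns, temporal_pc=temporal / nt,
                    which_pc=which_pc)


def orient_modules_cross_subject(pcmod: PCModule, alpha: float = 0.05) -> PCModule:
    """Canonical sign for cross-subject averaging of PC modules.

    When one-sample t-tests find both the spatial and temporal module
    entries significantly different from 0 and both means are negative,
    both vectors flip; any other combination is left unchanged (flipping
    spatial and temporal together leaves every reconstruction invariant).
    """
    ps = sps.ttest_1samp(pcmod.spatial_pc, 0.0).pvalue
    pt = sps.ttest_1samp(pcmod.temporal_pc, 0.0).pvalue
    if (ps < alpha and pt < alpha
            and pcmod.spatial_pc.mean() < 0 and pcmod.temporal_pc.mean() < 0):
        return PCModule(
            spatial_pc=-pcmod.spatial_pc,
            temporal_pc=-pcmod.temporal_pc,
            which_pc=pcmod.which_pc,
            sign_flipped=True,
        )
    return pcmod
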