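"""Statistical layer: Tukey pairwise tests, one-way ANOVA, Bonferroni-
corrected one-sample t-tests with Cohen's d, and the threshold-robustness
correlation matrices of the trial-space scores."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .data import EMGTensor
from .exceptions import DegenerateInputError

__all__ = [
    "StatResult",
    "tukey_hsd",
    "anova_oneway",
    "ttest_bonferroni_d",
    "criteria_robustness",
]


@dataclass
class StatResult:
    """One comparison's statistic, p-values and effect size."""

    comparison: str
    statistic: float
    p_value: float
    p_corrected: float | None = None
    effect_size: float | None = None
    df: tuple[int, int] | int | None = None


def tukey_hsd(
    groups: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
) -> list[StatResult]:
    """All-pairs Tukey HSD on the pooled within-group variance.

    Returns one :class:`StatResult` per group pair with the studentized-
    range-based p-value.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need at least two groups with n >= 2 each")
    if all(a.var(ddof=1) == 0 for a in arrays):
        raise DegenerateInputError("zero within-group variance in every group")
    labels = (list(labels) if labels is not None
              else [f"g{i + 1}" for i in range(len(arrays))])
    res = sps.tukey_hsd(*arrays)
    out = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            out.append(StatResult(
                comparison=f"{labels[i]} vs {labels[j]}",
                statistic=float(res.statistic[i, j]),
                p_value=float(res.pvalue[i, j]),
            ))
    return out


def anova_oneway(y: np.ndarray, group_labels: np.ndarray) -> StatResult:
    """One-way ANOVA F test with its (C - 1, N - C) degrees of freedom."""
    y = np.asarray(y, dtype=float)
    group_labels = np.asarray(group_labels)
    levels = np.unique(group_labels)
    samples = [y[group_labels == g] for g in levels]
    if levels.size < 2 or any(s.size < 2 for s in samples):
        raise ValueError("need at least two groups with n >= 2 each")
    f, p = sps.f_oneway(*samples)
    df = (int(levels.size - 1), int(y.size - levels.size))
    return StatResult(comparison="between groups", statistic=float(f),
                      p_value=float(p), df=df)


def ttest_bonferroni_d(
    per_subject_values: np.ndarray,
    m: int | None = None,
    labels: Sequence[str] | None = None,
) -> list[StatResult]:
    """Per-element one-sample t vs 0 across subjects, Bonferroni corrected.

    ``per_subject_values`` is (n_subjects, n_elements); ``m`` defaults to
    the number of elements. Cohen's d is mean/sd across subjects. A
    zero-variance element with nonzero mean is an exact, infinitely
    large effect: it reports d = +/-inf with raw p = 0; with zero mean it
    reports d = 0, p = 1.
    """
    vals = np.atleast_2d(np.asarray(per_subject_values, dtype=float))
    n, n_el = vals.shape
    if n < 2:
        raise ValueError("need at least two subjects")
    m = n_el if m is None else int(m)
    labels = (list(labels) if labels is not None
              else [f"e{i + 1}" for i in range(n_el)])
    out = []
    for i in range(n_el):
        col = vals[:, i]
        sd = col.std(ddof=1)
        mean = col.mean()
        if sd == 0:
            stat = 0.0 if mean == 0 else np.inf * np.sign(mean)
            p = 1.0 if mean == 0 else 0.0
            d = 0.0 if mean == 0 else float(np.inf * np.sign(mean))
        else:
            stat, p = sps.ttest_1samp(col, 0.0)
            d = float(mean / sd)
        out.append(StatResult(
            comparison=labels[i], statistic=float(stat), p_value=float(p),
            p_corrected=float(min(1.0, m * p)), effect_size=d, df=n - 1))
    return out


def criteria_robustness(
    tensor: EMGTensor | np.ndarray,
    thresholds: Sequence[float] = (0.70, 0.75, 0.80, 0.85),
    pipeline_fn: Callable[[EMGTensor | np.ndarray, float], dict] | None = None,
    **fit_kwargs,
) -> dict[str, np.ndarray]:
    """|Pearson r| of gate and fine scores across variance criteria.

    For each threshold the pipeline selects a rank, fits the CP model and
    orients the trial-space scores; the matrices hold the absolute
    correlation between the K-length score vectors of every threshold
    pair (symmetric, unit diagonal). ``pipeline_fn(tensor, threshold)``
    must return a dict with ``gate_scores`` and ``fine_scores``; the
    default shares one rank scan across thresholds, since each threshold
    reads its rank off the same fitted variance curve.

    Returns ``{"thresholds", "gate", "fine"}`` where ``gate`` aligns with
    PC1 and ``fine`` with PC2 in typical subjects.
    """
    thresholds = sorted(thresholds)
    if pipeline_fn is None:
        from .pipeline import threshold_scores_shared_scan
        runs = threshold_scores_shared_scan(tensor, thresholds, **fit_kwargs)
    else:
        runs = [pipeline_fn(tensor, th) for th in thresholds]
    n = len(thresholds)
    mats = {"gate": np.eye(n), "fine": np.eye(n)}
    for key in ("gate", "fine"):
        vectors = [np.asarray(r[f"{key}_scores"], dtype=float) for r in runs]
        for v in vectors:
            if np.std(v) == 0:
                raise DegenerateInputError(
                    "constant score vector: correlation undefined")
        for i in range(n):
            for j in range(i + 1, n):
                r = np.corrcoef(vectors[i], vectors[j])[0, 1]
                mats[key][i, j] = mats[key][j, i] = abs(float(r))
    return {"thresholds": np.asarray(thresholds, dtype=float), **mats}
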