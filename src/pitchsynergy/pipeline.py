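"""End-to-end orchestration: simulate/load -> decompose -> trial space ->
classify -> stats, with a reproducible JSON manifest.

The pipeline mirrors the analysis order of the study it implements:
select the CP rank by the 80% uncentered-R^2 criterion, fit the
nonnegative CP model, extract and orient the two trial-space dimensions,
reconstruct the PC-associated modules, fit the effort classifier with
repeated hold-out, and run the statistical layer on ball speeds and
scores. Given the same config (including seeds) two runs produce
identical manifests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as psio
from .classify import baseline_error, evaluate_holdout, fit_tree
from .data import EMGTensor
from .decompose import select_rank
from .exceptions import InvalidConfigError
from .preprocess import minmax_normalize, qc_subject
from .stats import anova_oneway, tukey_hsd
from .synth import ScenarioConfig, generate_ground_truth, render_tensor
from .trialspace import (
    orient_and_assign_roles,
    orient_modules_cross_subject,
    pc_associated_modules,
    pca_trial_components,
)

logger = logging.getLogger("pitchsynergy")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "threshold_scores_shared_scan"]


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    Either ``tensor_csv`` points at a long-format tensor file or
    ``scenario`` describes a synthetic subject to simulate.
    """

    tensor_csv: str | None = None
    scenario: ScenarioConfig | None = None
    seed: int = 0
    threshold: float = 0.80
    r_max: int = 20
    restarts: int = 10
    tol: float = 1e-8
    max_iter: int = 2000
    normalize: bool = False          # synthetic tensors are already on [0, 1]
    run_qc: bool = True
    holdout_fraction: float = 0.30
    holdout_repeats: int = 100
    min_leaf_grid: Sequence[int] = field(default_factory=lambda: range(1, 11))
    out_dir: str | None = None

    def validate(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise InvalidConfigError(
                f"threshold must be in (0, 1), got {self.threshold}")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise InvalidConfigError("holdout fraction must be in (0, 1)")
        if self.tensor_csv is None and self.scenario is None:
            self.scenario = ScenarioConfig()
        if self.tensor_csv is not None and self.scenario is not None:
            raise InvalidConfigError(
                "give either tensor_csv or a simulation scenario, not both")


@dataclass
class PipelineResult:
    tensor: EMGTensor
    scan: "object"
    model: "object"
    trial_pca: "object"
    gate_module: "object"
    fine_module: "object"
    tree: "object"
    holdout_error: float
    baseline: float
    stats: dict
    manifest: dict


def _config_manifest(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["min_leaf_grid"] = [int(v) for v in config.min_leaf_grid]
    if config.scenario is not None:
        s = dataclasses.asdict(config.scenario)
        for key, val in s.items():
            if isinstance(val, np.ndarray):
                s[key] = val.tolist()
        d["scenario"] = s
    return d


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis for one subject; optionally write outputs."""
    config.validate()
    if config.tensor_csv is not None:
        logger.info("loading tensor from %s", config.tensor_csv)
        tensor = psio.read_tensor_csv(config.tensor_csv)
    else:
        logger.info("simulating scenario with seed %d", config.seed)
        gt = generate_ground_truth(config.scenario, seed=config.seed)
        tensor = render_tensor(gt, seed=config.seed)

    qc = qc_subject(tensor) if config.run_qc else None
    if qc is not None and not qc.keep:
        logger.warning("QC excludes subject %s (%d flagged muscles)",
                       tensor.subject_id, len(qc.flagged_muscles))
    if config.normalize:
        tensor = minmax_normalize(tensor)

    logger.info("scanning ranks up to %d at threshold %.2f",
                config.r_max, config.threshold)
    scan = select_rank(
        tensor, threshold=config.threshold, r_max=config.r_max,
        restarts=config.restarts, seed=config.seed, tol=config.tol,
        max_iter=config.max_iter)
    model = scan.model()

    pca = orient_and_assign_roles(
        pca_trial_components(model.trial), tensor.effort_labels)
    gate_mod = orient_modules_cross_subject(
        pc_associated_modules(model, pca, pca.role["gate"]))
    fine_mod = orient_modules_cross_subject(
        pc_associated_modules(model, pca, pca.role["fine"]))

    scores = np.column_stack(
        [pca.role_scores("gate"), pca.role_scores("fine")])
    tree = fit_tree(scores, tensor.effort_labels,
                    min_leaf_grid=config.min_leaf_grid, seed=config.seed)
    holdout = evaluate_holdout(
        scores, tensor.effort_labels, fraction=config.holdout_fraction,
        repeats=config.holdout_repeats, seed=config.seed,
        min_leaf_size=tree.min_leaf_size)
    _, counts = np.unique(tensor.effort_labels, return_counts=True)
    base = baseline_error(counts)

    stats: dict = {}
    if tensor.ball_speeds is not None:
        groups = [tensor.ball_speeds[tensor.effort_labels == e]
                  for e in (50, 80, 100)]
        stats["ball_speed_tukey"] = tukey_hsd(groups, ["50%", "80%", "100%"])
        stats["ball_speed_anova"] = anova_oneway(
            tensor.ball_speeds, tensor.effort_labels)
    stats["gate_scores_tukey"] = tukey_hsd(
        [pca.role_scores("gate")[tensor.effort_labels == e]
         for e in (50, 80, 100)], ["50%", "80%", "100%"])

    manifest = {
        "config": _config_manifest(config),
        "subject_id": tensor.subject_id,
        "tensor_shape": list(tensor.X.shape),
        "qc": None if qc is None else {
            "keep": qc.keep, "flagged_muscles": qc.flagged_muscles},
        "rank_scan": {
            "ranks": scan.ranks.tolist(),
            "r2": [round(float(v), 12) for v in scan.r2],
            "selected_rank": scan.selected_rank,
            "reached": scan.reached,
        },
        "lambdas": [round(float(v), 12) for v in model.lambdas],
        "trial_space": {
            "explained_fraction_2d": round(float(pca.explained_fraction_2d), 12),
            "role": pca.role,
            "swap_applied": pca.swap_applied,
        },
        "classification": {
            "min_leaf_size": tree.min_leaf_size,
            "training_error": round(tree.training_error, 12),
            "holdout_error": round(holdout, 12),
            "holdout_repeats": config.holdout_repeats,
            "baseline_error": round(base, 12),
        },
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        psio.write_tensor_csv(tensor, out / "tensor.csv")
        psio.write_cp_model(model, out / "model",
                            muscle_labels=tensor.muscle_labels)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
        logger.info("wrote results to %s", out)

    return PipelineResult(
        tensor=tensor, scan=scan, model=model, trial_pca=pca,
        gate_module=gate_mod, fine_module=fine_mod, tree=tree,
        holdout_error=holdout, baseline=base, stats=stats, manifest=manifest)


def threshold_scores_shared_scan(
    tensor: EMGTensor | np.ndarray,
    thresholds: Sequence[float],
    effort_labels: np.ndarray | None = None,
    r_max: int = 20,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> list[dict]:
    """Oriented gate/fine scores at several variance criteria.

    Ranks are scanned once up to the strictest threshold; each threshold
    then selects the smallest rank reaching it on that shared curve and
    reuses the corresponding fitted model.
    """
    if effort_labels is None:
        if not isinstance(tensor, EMGTensor):
            raise ValueError("effort_labels required for a bare array")
        effort_labels = tensor.effort_labels
    scan = select_rank(
        tensor, threshold=max(thresholds), r_max=r_max, restarts=restarts,
        seed=seed, tol=tol, max_iter=max_iter)
    out = []
    for th in thresholds:
        rank, reached = scan.select(th)
        model = scan.model(rank)
        pca = orient_and_assign_roles(
            pca_trial_components(model.trial), effort_labels)
        out.append({
            "threshold": th,
            "selected_rank": rank,
            "reached": reached,
            "gate_scores": pca.role_scores("gate"),
            "fine_scores": pca.role_scores("fine"),
            "pca": pca,
            "model": model,
        })
    return out
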