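"""Registration accuracy metrics and few-shot / regime comparisons.

TRE (target registration error) is the root-mean-square Euclidean
distance between corresponding landmark centroids, in mm; landmark
masks are warped by the predicted displacement field and centroids are
recomputed (pull-back-native convention).  DSC is the hard Dice overlap
of the warped source gland against the entire ground-truth target
gland, both thresholded at 0.5.

``evaluate_few_shot`` reproduces the sweep protocol: at F acquired
frames the network has received F - F_min adaptation updates (the last
one on F - 1 frames) and runs inference on all F frames, yielding one
curve row per F.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_spatial import DisplacementField, LandmarkSet, Volume, warp, warp_array
from .interaction import build_sweep_schedule, gland_slice_extent
from .metalearn import RegistrationMetaProblem, _sparse_update, make_optimizer
from .network import NetworkWeights

__all__ = ["FewShotCurve", "dsc", "tre", "warp_landmarks",
           "evaluate_few_shot", "evaluate_at_frames", "compare_regimes"]


def dsc(warped_label: Volume, target_label: Volume, threshold: float = 0.5) -> float:
    """Hard Dice 2|A∩B|/(|A|+|B|) after thresholding both labels."""
    if warped_label.shape != target_label.shape:
        raise ValueError(
            f"grids differ: {warped_label.shape} vs {target_label.shape}")
    a = warped_label.values > threshold
    b = target_label.values > threshold
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("both labels empty after thresholding; DSC set to 0")
        return 0.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def tre(warped_landmarks: LandmarkSet, target_landmarks: LandmarkSet,
        spacing_mm: float) -> float:
    """RMS distance between corresponding landmark centroids, in mm."""
    if len(warped_landmarks) != len(target_landmarks):
        raise ValueError("landmark sets have different lengths")
    if len(warped_landmarks) == 0:
        raise ValueError("landmark sets are empty")
    ca = warped_landmarks.centroids()
    cb = target_landmarks.centroids()
    d2 = np.sum((ca - cb) ** 2, axis=1)
    return float(np.sqrt(d2.mean()) * spacing_mm)


def warp_landmarks(landmarks: LandmarkSet, ddf: DisplacementField) -> LandmarkSet:
    return LandmarkSet([warp_array(m, ddf.vectors) for m in landmarks.landmarks])


@dataclass
class FewShotCurve:
    """Per-F metric lists over a shared test cohort."""

    f_values: list[int]
    grad_updates: list[int]
    tre_mm: np.ndarray  # (n_rows, n_tasks)
    dsc_vals: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "F": self.f_values,
            "Grad. Updates": self.grad_updates,
            "Median TRE": np.median(self.tre_mm, axis=1),
            "TRE SD": np.std(self.tre_mm, axis=1),
            "Mean DSC": np.mean(self.dsc_vals, axis=1),
            "DSC SD": np.std(self.dsc_vals, axis=1),
        })

    def spearman_f_vs_tre(self) -> float:
        """Spearman rank correlation between F and median TRE."""
        rho, _ = stats.spearmanr(self.f_values, np.median(self.tre_mm, axis=1))
        return float(rho)


def _task_metrics(task, ddf: DisplacementField) -> tuple[float, float]:
    warped_gland = warp(task.source_gland, ddf)
    d = dsc(warped_gland, task.target_gland)
    warped_lm = warp_landmarks(task.source_landmarks, ddf)
    t = tre(warped_lm, task.target_landmarks, task.source_img.spacing_mm)
    return t, d


def evaluate_few_shot(problem: RegistrationMetaProblem, w: NetworkWeights,
                      test_tasks: list, f_min: int, f_max: int,
                      beta_task: float, inner_optimizer: str = "adam",
                      adapt: bool = True) -> FewShotCurve:
    """Run the sweep protocol per task and record TRE/DSC at every F.

    With ``adapt=False`` the weights are frozen (no few-shot learning)
    and only the inference input grows with F.
    """
    f_values = list(range(f_min, f_max + 1))
    n_rows = len(f_values)
    tre_mm = np.empty((n_rows, len(test_tasks)))
    dsc_vals = np.empty((n_rows, len(test_tasks)))
    for j, task in enumerate(test_tasks):
        n_slices = task.target_img.shape[task.target_img.slice_axis]
        extent = gland_slice_extent(task.target_gland)
        schedule = build_sweep_schedule(n_slices, f_min, f_max, extent)
        order = schedule.inference_frames
        wt = dict(w)
        opt = make_optimizer(inner_optimizer)
        for i, f in enumerate(f_values):
            if adapt and f > f_min:
                sample = problem.interaction_at(task, order[:f - 1])
                wt, _ = _sparse_update(problem, wt, task, sample, beta_task, opt)
            ddf = problem.predict(wt, task, order[:f])
            tre_mm[i, j], dsc_vals[i, j] = _task_metrics(task, ddf)
    updates = [(f - f_min) if adapt else 0 for f in f_values]
    return FewShotCurve(f_values, updates, tre_mm, dsc_vals)


def evaluate_at_frames(problem: RegistrationMetaProblem, w: NetworkWeights,
                       test_tasks: list, f_max: int, f_min: int = 2
                       ) -> tuple[np.ndarray, np.ndarray]:
    """TRE/DSC per task at the full F_max inference state, frozen weights."""
    tre_mm = np.empty(len(test_tasks))
    dsc_vals = np.empty(len(test_tasks))
    for j, task in enumerate(test_tasks):
        n_slices = task.target_img.shape[task.target_img.slice_axis]
        extent = gland_slice_extent(task.target_gland)
        schedule = build_sweep_schedule(n_slices, f_min, f_max, extent)
        ddf = problem.predict(w, task, schedule.inference_frames)
        tre_mm[j], dsc_vals[j] = _task_metrics(task, ddf)
    return tre_mm, dsc_vals


def _identity_ddf(task) -> DisplacementField:
    return DisplacementField.zeros(task.source_gland.shape)


def _centroid_ddf(task) -> DisplacementField:
    """Constant pull-back field aligning the source gland centroid onto
    the target's: u = c_src - c_tgt."""
    def centroid(v: Volume) -> np.ndarray:
        m = v.values
        idx = np.indices(m.shape, dtype=np.float64)
        return (idx * m).sum(axis=(1, 2, 3)) / m.sum()

    u = centroid(task.source_gland) - centroid(task.target_gland)
    grid = task.source_gland.shape
    return DisplacementField(np.broadcast_to(
        u[:, None, None, None], (3, *grid)).copy())


def compare_regimes(test_tasks: list, problem: RegistrationMetaProblem,
                    meta_weights: NetworkWeights | None,
                    random_weights: NetworkWeights | None,
                    f_min: int, f_max: int, beta_task: float,
                    regimes: tuple[str, ...] = (
                        "no_registration", "centroid_alignment",
                        "meta_fewshot", "meta_only", "random_fewshot"),
                    extra_weights: dict[str, NetworkWeights] | None = None,
                    ) -> pd.DataFrame:
    """Median TRE / mean DSC per training-and-adaptation regime on a
    shared test cohort (network regimes report the F_max state)."""
    rows = {}

    def closed_form(make_ddf):
        t = np.empty(len(test_tasks)); d = np.empty(len(test_tasks))
        for j, task in enumerate(test_tasks):
            t[j], d[j] = _task_metrics(task, make_ddf(task))
        return t, d

    for name in regimes:
        if name == "no_registration":
            t, d = closed_form(_identity_ddf)
        elif name == "centroid_alignment":
            t, d = closed_form(_centroid_ddf)
        elif name in ("meta_fewshot", "random_fewshot"):
            w = meta_weights if name == "meta_fewshot" else random_weights
            if w is None:
                continue
            curve = evaluate_few_shot(problem, w, test_tasks, f_min, f_max,
                                      beta_task)
            t, d = curve.tre_mm[-1], curve.dsc_vals[-1]
        elif name == "meta_only":
            if meta_weights is None:
                continue
            t, d = evaluate_at_frames(problem, meta_weights, test_tasks,
                                      f_max, f_min)
        elif extra_weights and name in extra_weights:
            curve = evaluate_few_shot(problem, extra_weights[name], test_tasks,
                                      f_min, f_max, beta_task)
            t, d = curve.tre_mm[-1], curve.dsc_vals[-1]
        else:
            raise ValueError(f"unknown regime {name!r}")
        rows[name] = {"median_tre_mm": float(np.median(t)),
                      "mean_dsc": float(np.mean(d)),
                      "tre_sd": float(np.std(t)),
                      "dsc_sd": float(np.std(d)),
                      "n_tasks": len(test_tasks)}
    return pd.DataFrame(rows).T
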