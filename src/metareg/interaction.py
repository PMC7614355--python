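"""Simulation of interactive sparse-frame acquisition.

During meta-training, an interaction is a random subset of F acquisition
frames (2D slices along the volume's slice axis), drawn from the slices
that intersect the gland segmentation — the clinically plausible part of
a probe sweep.  At meta-test time acquisition is deterministic: a single
sweep visits F_max positions uniformly spread across the gland, in
descending slice order (a right-to-left sweep), and each few-shot
gradient update adds one frame to a nested schedule.

The first update uses F_min frames (two frames give minimal spatial
context); the final update uses F_max - 1 frames, and inference runs
with all F_max, so the number of gradient updates is F_max - F_min.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core_spatial import Volume

__all__ = [
    "InteractionSample",
    "SweepSchedule",
    "apply_mask",
    "sample_training_interaction",
    "build_sweep_schedule",
    "gland_slice_extent",
]


@dataclass(frozen=True)
class InteractionSample:
    """One interaction state: acquired frames and the masked target data."""

    frames: tuple[int, ...]
    target_image_masked: Volume
    target_label_masked: Volume
    mask: Volume

    @property
    def num_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class SweepSchedule:
    """Nested frame sets, one per few-shot update, plus the inference set."""

    steps: tuple[tuple[int, ...], ...]
    inference_frames: tuple[int, ...]

    @property
    def num_updates(self) -> int:
        return len(self.steps)


def _slice_mask(shape: tuple[int, int, int], axis: int,
                frames: tuple[int, ...]) -> np.ndarray:
    m = np.zeros(shape)
    idx = [slice(None)] * 3
    idx[axis] = list(frames)
    m[tuple(idx)] = 1.0
    return m


def apply_mask(img: Volume, lab: Volume, frames) -> InteractionSample:
    """Zero out all slices except ``frames`` along the slice axis.

    Idempotent: re-masking with the same frames is a no-op.  Raises on
    out-of-range frame indices.
    """
    frames = tuple(sorted(int(f) for f in frames))
    n = img.shape[img.slice_axis]
    if not frames:
        raise ValueError("at least one frame is required")
    if frames[0] < 0 or frames[-1] >= n:
        raise ValueError(f"frame indices {frames} out of range for {n} slices")
    if len(set(frames)) != len(frames):
        raise ValueError(f"duplicate frame indices in {frames}")
    m = _slice_mask(img.shape, img.slice_axis, frames)
    return InteractionSample(
        frames=frames,
        target_image_masked=img.with_values(img.values * m),
        target_label_masked=lab.with_values(lab.values * m),
        mask=Volume(m, img.spacing_mm, img.slice_axis, is_label=True),
    )


def gland_slice_extent(gland: Volume, threshold: float = 0.5) -> tuple[int, int]:
    """Inclusive slice-index range intersecting the gland label."""
    axes = tuple(a for a in range(3) if a != gland.slice_axis)
    hit = np.where((gland.values > threshold).any(axis=axes))[0]
    if hit.size == 0:
        raise ValueError("gland label is empty; no candidate slices")
    return int(hit[0]), int(hit[-1])


def sample_training_interaction(
    target_img: Volume,
    target_lab: Volume,
    f_min: int,
    f_max: int,
    seed: int | np.random.Generator = 0,
) -> InteractionSample:
    """Random training interaction: F ~ U[F_min, F_max] frames drawn
    without replacement from gland-intersecting slices."""
    if not (1 <= f_min <= f_max):
        raise ValueError(f"need 1 <= F_min <= F_max, got ({f_min}, {f_max})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = gland_slice_extent(target_lab)
    candidates = np.arange(lo, hi + 1)
    if candidates.size < f_min:
        raise ValueError(
            f"only {candidates.size} candidate slices but F_min={f_min}")
    f = int(rng.integers(f_min, min(f_max, candidates.size) + 1))
    frames = rng.choice(candidates, size=f, replace=False)
    return apply_mask(target_img, target_lab, frames)


def build_sweep_schedule(num_slices: int, f_min: int, f_max: int,
                         gland_extent: tuple[int, int]) -> SweepSchedule:
    """Deterministic single-sweep schedule.

    F_max positions are spaced uniformly across ``gland_extent``
    (inclusive) and visited in descending slice order.  Update j uses the
    first F_min + j frames (j = 0 .. F_max - F_min - 1); inference uses
    all F_max.
    """
    lo, hi = gland_extent
    if not (0 <= lo <= hi < num_slices):
        raise ValueError(f"extent {gland_extent} invalid for {num_slices} slices")
    if hi - lo + 1 < f_max:
        raise ValueError(
            f"gland extent spans {hi - lo + 1} slices < F_max={f_max}")
    if not (1 <= f_min <= f_max):
        raise ValueError(f"need 1 <= F_min <= F_max, got ({f_min}, {f_max})")
    positions = np.unique(np.round(np.linspace(lo, hi, f_max)).astype(int))
    if positions.size != f_max:  # extent barely fits; fall back to a dense run
        positions = np.arange(hi - f_max + 1, hi + 1)
    order = tuple(int(p) for p in positions[::-1])  # right-to-left sweep
    steps = tuple(order[:f_min + j] for j in range(f_max - f_min))
    return SweepSchedule(steps=steps, inference_frames=order)


def schedule_to_json(schedule: SweepSchedule) -> str:
    return json.dumps({
        "steps": [sorted(s) for s in schedule.steps],
        "inference_frames": sorted(schedule.inference_frames),
    })
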