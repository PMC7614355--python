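"""Synthetic per-subject registration tasks.

Each task emulates one subject's paired volumes: a smooth gland-like
foreground (a randomized superellipsoid) visible in both "modalities"
under very different renderings, a known smooth non-rigid deformation
between the pair, gland segmentations on both sides, and 2-4 small
landmark blobs with exact correspondence (two at the gland poles along
the slice axis, emulating apex/base, plus random interior structures).

The target rendering uses an inverted, compressed contrast curve and
multiplicative speckle-like noise so that intensity similarity between
the pair is deliberately uninformative: the label-driven loss has to do
the work, mirroring the multimodal setting the method targets.

The ground-truth field ``true_ddf`` is a pull-back field on the target
grid: target geometry at x equals source geometry sampled at x + u(x).
It combines a random translation with a Gaussian-smoothed random
control-point residual and is guaranteed fold-free (positive Jacobian
determinant of x + u everywhere); violating draws are rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_spatial import DisplacementField, LandmarkSet, Volume, warp
from .losses import soft_dice

__all__ = ["TaskDataset", "GeneratorParams", "generate_task", "generate_cohort"]

DEFAULT_GRID = (32, 32, 32)


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for the synthetic cohort."""

    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    spacing_mm: float = 1.0
    deform_scale: float | None = None  # peak residual displacement, voxels;
                                       # None -> 15% of the smallest grid extent
    translation_scale: float = 0.12  # fraction of grid extent; together with
                                     # the residual this yields unregistered
                                     # misalignments comparable to the gland
                                     # radius, as in the clinical setting
    edge_width: float = 0.06     # gland boundary softness, fraction of radius
    landmark_radius_vox: float = 2.0
    noise_source: float = 0.03   # additive noise SD, source rendering
    speckle: float = 0.35        # multiplicative noise amplitude, target

    def resolved_deform_scale(self) -> float:
        if self.deform_scale is None:
            return 0.15 * min(self.grid_shape)
        return self.deform_scale


@dataclass(frozen=True)
class TaskDataset:
    """One subject's registration task; true_ddf is held-out ground truth."""

    source_img: Volume
    target_img: Volume
    source_gland: Volume
    target_gland: Volume
    source_landmarks: LandmarkSet
    target_landmarks: LandmarkSet
    true_ddf: DisplacementField
    subject_seed: int
    landmark_labels: tuple[tuple[Volume, Volume], ...] = field(default=())


def _superellipsoid(grid: tuple[int, int, int], centre: np.ndarray,
                    radii: np.ndarray, power: float, edge: float) -> np.ndarray:
    idx = np.indices(grid, dtype=np.float64)
    r = np.zeros(grid)
    for ax in range(3):
        r += np.abs((idx[ax] - centre[ax]) / radii[ax]) ** power
    r = r ** (1.0 / power)
    return 1.0 / (1.0 + np.exp((r - 1.0) / edge))


def _ball(grid: tuple[int, int, int], centre: np.ndarray, radius: float) -> np.ndarray:
    idx = np.indices(grid, dtype=np.float64)
    d2 = sum((idx[a] - centre[a]) ** 2 for a in range(3))
    return (d2 <= radius ** 2).astype(np.float64)


def _smooth_random_field(rng: np.random.Generator, grid: tuple[int, int, int],
                         magnitude: float, translation: np.ndarray) -> np.ndarray:
    """Translation plus smoothed control-point residual, peak ~= magnitude."""
    u = np.empty((3, *grid))
    coarse = rng.normal(size=(3, 4, 4, 4))
    for c in range(3):
        z = ndimage.zoom(coarse[c], np.asarray(grid) / 4.0, order=3)
        z = ndimage.gaussian_filter(z, sigma=2.0, mode="nearest")
        u[c] = z
    peak = np.abs(u).max()
    if peak > 0:
        u *= magnitude / peak
    return u + translation[:, None, None, None]


def _jacobian_det(u: np.ndarray) -> np.ndarray:
    """det(I + du/dx) by central differences (interior voxels)."""
    g = np.empty((3, 3) + u.shape[1:])
    for c in range(3):
        for ax in range(3):
            g[c, ax] = np.gradient(u[c], axis=ax)
    jac = np.eye(3)[:, :, None, None, None] + g
    return (jac[0, 0] * (jac[1, 1] * jac[2, 2] - jac[1, 2] * jac[2, 1])
            - jac[0, 1] * (jac[1, 0] * jac[2, 2] - jac[1, 2] * jac[2, 0])
            + jac[0, 2] * (jac[1, 0] * jac[2, 1] - jac[1, 1] * jac[2, 0]))


def _render_source(gland: np.ndarray, rng: np.random.Generator,
                   p: GeneratorParams) -> np.ndarray:
    tex = ndimage.gaussian_filter(rng.normal(size=gland.shape), sigma=2.0)
    img = 0.2 + 0.6 * gland + 0.15 * tex
    img = ndimage.gaussian_filter(img, sigma=0.7)
    img += rng.normal(0.0, p.noise_source, gland.shape)
    return _norm01(img)


def _render_target(gland: np.ndarray, rng: np.random.Generator,
                   p: GeneratorParams) -> np.ndarray:
    # inverted, compressed contrast: gland darker than background
    img = 0.75 - 0.45 * gland ** 0.7
    speckle = ndimage.gaussian_filter(rng.exponential(1.0, gland.shape), sigma=0.8)
    img = img * (1.0 + p.speckle * (speckle - speckle.mean()))
    return _norm01(img)


def _norm01(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo + 1e-12)


def generate_task(subject_seed: int,
                  params: GeneratorParams | None = None) -> TaskDataset:
    """Deterministically generate one subject's task from its seed."""
    p = params or GeneratorParams()
    grid = tuple(p.grid_shape)
    rng = np.random.default_rng(subject_seed)
    extent = np.asarray(grid, dtype=np.float64)

    centre = extent / 2 + rng.uniform(-0.03, 0.03, 3) * extent
    radii = extent * rng.uniform(0.24, 0.33, 3)
    power = rng.uniform(1.8, 3.0)
    gland_src = _superellipsoid(grid, centre, radii, power, p.edge_width)

    # landmarks: apex/base poles along the slice axis + interior blobs
    n_extra = int(rng.integers(0, 3))  # total 2-4 landmarks
    lm_centres = [centre.copy(), centre.copy()]
    lm_centres[0][0] = centre[0] - 0.8 * radii[0]
    lm_centres[1][0] = centre[0] + 0.8 * radii[0]
    for _ in range(n_extra):
        d = rng.uniform(-0.55, 0.55, 3)
        lm_centres.append(centre + d * radii)
    src_masks = [_ball(grid, c, p.landmark_radius_vox) for c in lm_centres]

    # ground-truth pull-back deformation, resampled fold-free
    translation = rng.uniform(-1.0, 1.0, 3) * p.translation_scale * extent
    magnitude = p.resolved_deform_scale()
    for _ in range(20):
        u = _smooth_random_field(rng, grid, magnitude, translation)
        if magnitude == 0:
            u = np.zeros_like(u)
        if _jacobian_det(u).min() > 0.05:
            break
        magnitude *= 0.7
    else:
        raise RuntimeError(f"could not draw a fold-free field for seed {subject_seed}")
    true_ddf = DisplacementField(u)

    def vol(a, is_label=False):
        return Volume(np.clip(a, 0, 1) if is_label else a, p.spacing_mm, 0, is_label)

    src_gland_v = vol(gland_src, is_label=True)
    tgt_gland_v = warp(src_gland_v, true_ddf)
    src_lm_v = [vol(m, is_label=True) for m in src_masks]
    tgt_lm_v = [warp(m, true_ddf) for m in src_lm_v]

    source_img = vol(_render_source(gland_src, rng, p))
    target_img = vol(_render_target(tgt_gland_v.values, rng, p))

    task = TaskDataset(
        source_img=source_img,
        target_img=target_img,
        source_gland=src_gland_v,
        target_gland=tgt_gland_v,
        source_landmarks=LandmarkSet([v.values for v in src_lm_v]),
        target_landmarks=LandmarkSet([v.values for v in tgt_lm_v]),
        true_ddf=true_ddf,
        subject_seed=int(subject_seed),
        landmark_labels=tuple(zip(src_lm_v, tgt_lm_v)),
    )
    _check_construction(task)
    return task


def _check_construction(task: TaskDataset) -> None:
    d = soft_dice(warp(task.source_gland, task.true_ddf), task.target_gland)
    if d < 0.95:
        raise AssertionError(f"construction check failed: warped-gland Dice {d:.3f}")


def subject_seed_for(base_seed: int, index: int, split: str) -> int:
    ss = np.random.SeedSequence([int(base_seed), 0 if split == "train" else 1,
                                 int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_cohort(n_train: int, n_test: int, base_seed: int,
                    params: GeneratorParams | None = None
                    ) -> tuple[list[TaskDataset], list[TaskDataset]]:
    """Disjoint train/test task lists with per-subject derived seeds."""
    if n_train < 1 or n_test < 1:
        raise ValueError("cohort sizes must be >= 1")
    train = [generate_task(subject_seed_for(base_seed, i, "train"), params)
             for i in range(n_train)]
    test = [generate_task(subject_seed_for(base_seed, i, "test"), params)
            for i in range(n_test)]
    return train, test
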