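"""Volumes, displacement fields and the spatial primitives shared by all
other modules: backward trilinear warping, isotropic Gaussian smoothing
and paired random-affine augmentation.

Conventions
-----------
* Grids are 0-based voxel-index grids; spacing is isotropic, in mm.
* Displacement fields are in **voxel units on the target grid** and are
  pull-back fields: ``warped(x) = source(x + u(x))``.  Spacing enters
  only when converting smoothing scales (mm) to voxels and registration
  errors to mm.
* Warping clamps to the volume edge; Gaussian filtering reflects at the
  boundary by default (kernel truncated at 3 sigma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from . import _autodiff as ad

__all__ = [
    "Volume",
    "DisplacementField",
    "LandmarkSet",
    "warp",
    "warp_array",
    "gaussian_filter3d",
    "random_affine_pair",
    "AffineBounds",
    "read_nifti",
    "write_nifti",
]


@dataclass(frozen=True)
class Volume:
    """3D scalar grid with isotropic spacing.

    ``is_label`` marks probabilistic label maps, whose values must lie in
    [0, 1].  ``slice_axis`` is the grid axis along which 2D acquisition
    frames are indexed (axis 0 by convention).
    """

    values: np.ndarray
    spacing_mm: float = 1.0
    slice_axis: int = 0
    is_label: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite values")
        if self.spacing_mm <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError(f"slice_axis must be 0, 1 or 2, got {self.slice_axis}")
        if self.is_label and (v.min() < 0 or v.max() > 1):
            raise ValueError(
                f"label values must lie in [0, 1], got range "
                f"[{v.min():.3g}, {v.max():.3g}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, is_label: bool | None = None) -> "Volume":
        return Volume(values, self.spacing_mm, self.slice_axis,
                      self.is_label if is_label is None else is_label)


@dataclass(frozen=True)
class DisplacementField:
    """Dense per-voxel displacement u(x), shape (3, D, H, W), voxel units."""

    vectors: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=np.float64)
        object.__setattr__(self, "vectors", v)
        if v.ndim != 4 or v.shape[0] != 3:
            raise ValueError(f"expected shape (3, D, H, W), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[1:]

    @classmethod
    def zeros(cls, grid_shape: tuple[int, int, int]) -> "DisplacementField":
        return cls(np.zeros((3, *grid_shape)))


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered list of binary landmark masks, index-paired across volumes."""

    landmarks: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        masks = [np.asarray(m, dtype=np.float64) for m in self.landmarks]
        object.__setattr__(self, "landmarks", masks)
        for i, m in enumerate(masks):
            if m.ndim != 3:
                raise ValueError(f"landmark {i} is not a 3D mask")
            if not np.any(m > 0):
                raise ValueError(f"landmark {i} has no foreground voxels")

    def __len__(self) -> int:
        return len(self.landmarks)

    def centroids(self) -> np.ndarray:
        """Intensity-weighted centroids, shape (n_landmarks, 3), voxel units."""
        out = np.empty((len(self.landmarks), 3))
        for i, m in enumerate(self.landmarks):
            w = m.sum()
            idx = np.indices(m.shape, dtype=np.float64)
            out[i] = (idx * m).sum(axis=(1, 2, 3)) / w
        return out


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

def warp_array(values: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Backward-warp a raw (D,H,W) array by a (3,D,H,W) voxel-unit field."""
    return ad.warp3(values, ad.constant(vectors)).value


def warp(vol: Volume, ddf: DisplacementField) -> Volume:
    """Resample ``vol`` at x + u(x), trilinear, clamp-to-edge.

    The output lives on the same grid as the input; warping a label
    volume yields values in [0, 1] because trilinear weights are convex.
    """
    if ddf.grid_shape != vol.shape:
        raise ValueError(
            f"field grid {ddf.grid_shape} does not match volume grid {vol.shape}")
    out = warp_array(vol.values, ddf.vectors)
    if vol.is_label:
        out = np.clip(out, 0.0, 1.0)  # guard float round-off at the ends
    return vol.with_values(out)


# ---------------------------------------------------------------------------
# Gaussian smoothing
# ---------------------------------------------------------------------------

def gaussian_filter3d(vol: Volume, sigma_mm: float, mode: str = "reflect") -> Volume:
    """Isotropic Gaussian smoothing with standard deviation in mm.

    sigma is converted to voxels via the volume spacing; sigma_mm = 0
    returns the input unchanged.  ``mode='constant'`` gives the
    zero-padded variant used inside the training loss (an exactly
    self-adjoint operator).
    """
    if sigma_mm < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma_mm}")
    if sigma_mm == 0:
        return vol
    sig_vox = sigma_mm / vol.spacing_mm
    if mode == "constant":
        out = ad._blur_nd(vol.values, sig_vox)
    else:
        out = ndimage.gaussian_filter(
            vol.values, sigma=sig_vox, mode=mode, truncate=3.0)
    if vol.is_label:
        out = np.clip(out, 0.0, 1.0)
    return vol.with_values(out)


# ---------------------------------------------------------------------------
# random affine augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffineBounds:
    """Magnitude bounds for the sampled augmentation transform."""

    rotation_deg: float = 10.0
    scale: float = 0.1          # scale factors in [1 - scale, 1 + scale]
    shear: float = 0.05
    translation_frac: float = 0.05  # fraction of grid extent per axis


def _sample_affine(rng: np.random.Generator, bounds: AffineBounds,
                   shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Sample linear part A (3x3, det > 0) and translation t (voxels)."""
    for _ in range(100):
        angles = np.deg2rad(rng.uniform(-bounds.rotation_deg, bounds.rotation_deg, 3))
        rots = []
        for ax, th in enumerate(angles):
            r = np.eye(3)
            i, j = [a for a in range(3) if a != ax]
            r[i, i] = np.cos(th); r[i, j] = -np.sin(th)
            r[j, i] = np.sin(th); r[j, j] = np.cos(th)
            rots.append(r)
        rot = rots[0] @ rots[1] @ rots[2]
        scale = np.diag(rng.uniform(1 - bounds.scale, 1 + bounds.scale, 3))
        shear = np.eye(3)
        for i in range(3):
            for j in range(3):
                if i != j:
                    shear[i, j] = rng.uniform(-bounds.shear, bounds.shear)
        a = rot @ scale @ shear
        if np.linalg.det(a) > 0:
            t = rng.uniform(-bounds.translation_frac, bounds.translation_frac, 3)
            t *= np.asarray(shape)
            return a, t
    raise RuntimeError("could not sample an orientation-preserving affine")


def random_affine_pair(
    vol: Volume,
    lab: Volume,
    bounds: AffineBounds | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[Volume, Volume]:
    """Apply one shared random affine (det > 0, no flips) to image and label.

    The transform maps output voxel x to sampling location A(x - c) + c + t
    (c the grid centre), realised with trilinear resampling and edge
    clamping, matching :func:`warp`'s conventions.  The same seed
    reproduces the pair exactly.
    """
    if vol.shape != lab.shape:
        raise ValueError(f"image grid {vol.shape} != label grid {lab.shape}")
    bounds = bounds or AffineBounds()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, t = _sample_affine(rng, bounds, vol.shape)
    centre = (np.asarray(vol.shape, dtype=np.float64) - 1) / 2
    offset = centre - a @ centre + t

    def resample(v: Volume) -> Volume:
        out = ndimage.affine_transform(
            v.values, a, offset=offset, order=1, mode="nearest")
        if v.is_label:
            out = np.clip(out, 0.0, 1.0)
        return v.with_values(out)

    return resample(vol), resample(lab)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_nifti(path, is_label: bool = False, slice_axis: int = 0) -> Volume:
    """Load a NIfTI volume; spacing is taken from the header (isotropic)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-3):
        raise ValueError(f"anisotropic spacing {zooms} not supported")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if is_label:
        data = np.clip(data, 0.0, 1.0)
    return Volume(data, spacing_mm=float(zooms[0]), slice_axis=slice_axis,
                  is_label=is_label)


def write_nifti(vol: Volume, path) -> None:
    affine = np.diag([vol.spacing_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine), str(path))
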