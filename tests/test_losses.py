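"""Soft Dice, multiscale Dice, bending energy and the composite objective."""

import numpy as np
import pytest
from scipy import ndimage

from metareg.core_spatial import DisplacementField, Volume, gaussian_filter3d
from metareg.losses import (LossWeights, bending_energy, multiscale_dice,
                            registration_loss, soft_dice)


def label(arr):
    return Volume(np.asarray(arr, dtype=float), spacing_mm=1.0, is_label=True)


def block(grid, lo, hi):
    v = np.zeros(grid)
    v[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = 1.0
    return v


class TestSoftDice:
    def test_identical_nonempty_masks_give_one(self):
        a = label(block((6, 6, 6), (1, 1, 1), (4, 4, 4)))
        assert soft_dice(a, a) == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_masks_give_zero(self):
        a = label(block((6, 6, 6), (0, 0, 0), (2, 2, 2)))
        b = label(block((6, 6, 6), (4, 4, 4), (6, 6, 6)))
        assert soft_dice(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_hand_counted_shifted_block_is_half(self):
        # 2x2x1 blocks sharing 2 voxels: 2*2/(4+4) = 0.5
        a = label(block((5, 5, 1), (1, 1, 0), (3, 3, 1)))
        b = label(block((5, 5, 1), (2, 1, 0), (4, 3, 1)))
        assert soft_dice(a, b) == pytest.approx(0.5, rel=1e-6)

    def test_both_empty_returns_zero(self):
        z = label(np.zeros((4, 4, 4)))
        assert soft_dice(z, z) == 0.0

    def test_symmetric(self, rng):
        a = label(rng.uniform(0, 1, (5, 5, 5)))
        b = label(rng.uniform(0, 1, (5, 5, 5)))
        assert soft_dice(a, b) == soft_dice(b, a)


class TestMultiscaleDice:
    def test_identical_labels_give_one_at_any_scale_set(self, blob_volume):
        w = LossWeights(sigmas_mm=(0, 1, 2, 4))
        assert multiscale_dice(blob_volume, blob_volume, w) == pytest.approx(1.0, abs=1e-6)

    def test_sigma_zero_reduces_to_soft_dice(self, rng):
        a = label(rng.uniform(0, 1, (6, 6, 6)))
        b = label(rng.uniform(0, 1, (6, 6, 6)))
        w = LossWeights(sigmas_mm=(0,))
        assert multiscale_dice(a, b, w) == pytest.approx(soft_dice(a, b), rel=1e-12)

    def test_smoothing_increases_overlap_of_near_miss_labels(self):
        a = label(block((16, 16, 16), (4, 4, 4), (7, 7, 7)))
        b = label(block((16, 16, 16), (7, 7, 7), (10, 10, 10)))
        w = LossWeights(sigmas_mm=(0, 4))
        msd = multiscale_dice(a, b, w)
        plain = soft_dice(a, b)
        assert msd > plain
        # compositional oracle: independent zero-padded filtering + Dice
        d4a = gaussian_filter3d(a, 4.0, mode="constant")
        d4b = gaussian_filter3d(b, 4.0, mode="constant")
        expected = 0.5 * (plain + soft_dice(d4a, d4b))
        assert msd == pytest.approx(expected, rel=1e-9)

    def test_symmetry_under_argument_swap(self, rng):
        a = label(rng.uniform(0, 1, (8, 8, 8)))
        b = label(rng.uniform(0, 1, (8, 8, 8)))
        w = LossWeights(sigmas_mm=(0, 1, 2))
        assert multiscale_dice(a, b, w) == pytest.approx(multiscale_dice(b, a, w), rel=1e-12)

    def test_invariant_to_joint_whole_voxel_translation(self):
        a = label(block((20, 20, 20), (8, 8, 8), (11, 11, 11)))
        b = label(block((20, 20, 20), (9, 8, 8), (12, 11, 11)))
        w = LossWeights(sigmas_mm=(0, 2))
        shifted_a = label(np.roll(a.values, 2, axis=1))
        shifted_b = label(np.roll(b.values, 2, axis=1))
        assert multiscale_dice(a, b, w) == pytest.approx(
            multiscale_dice(shifted_a, shifted_b, w), rel=1e-6)

    def test_empty_sigma_set_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            LossWeights(sigmas_mm=())


class TestBendingEnergy:
    def test_zero_field(self):
        assert bending_energy(DisplacementField.zeros((5, 5, 5))) == 0.0

    def test_affine_field_has_zero_energy(self, rng):
        a = rng.normal(size=(3, 3)) * 0.3
        b = rng.normal(size=3)
        idx = np.indices((6, 6, 6), dtype=float)
        u = np.einsum("ij,jdhw->idhw", a, idx) + b[:, None, None, None]
        assert bending_energy(DisplacementField(u)) == pytest.approx(0.0, abs=1e-20)

    def test_quadratic_field_oracle(self):
        # u_x = x^2: d2u/dx2 = 2 everywhere, all other terms 0 -> energy 4
        idx = np.indices((7, 7, 7), dtype=float)
        u = np.zeros((3, 7, 7, 7))
        u[0] = idx[0] ** 2
        assert bending_energy(DisplacementField(u)) == pytest.approx(4.0, rel=1e-12)

    def test_brute_force_finite_difference_oracle(self, rng):
        u = rng.normal(size=(3, 5, 5, 5))
        total = 0.0
        for c in range(3):
            for z in range(1, 4):
                for y in range(1, 4):
                    for x in range(1, 4):
                        v = u[c]
                        dxx = v[z+1, y, x] - 2*v[z, y, x] + v[z-1, y, x]
                        dyy = v[z, y+1, x] - 2*v[z, y, x] + v[z, y-1, x]
                        dzz = v[z, y, x+1] - 2*v[z, y, x] + v[z, y, x-1]
                        dxy = (v[z+1, y+1, x] - v[z+1, y-1, x]
                               - v[z-1, y+1, x] + v[z-1, y-1, x]) / 4
                        dxz = (v[z+1, y, x+1] - v[z+1, y, x-1]
                               - v[z-1, y, x+1] + v[z-1, y, x-1]) / 4
                        dyz = (v[z, y+1, x+1] - v[z, y+1, x-1]
                               - v[z, y-1, x+1] + v[z, y-1, x-1]) / 4
                        total += (dxx**2 + dyy**2 + dzz**2
                                  + 2 * (dxy**2 + dxz**2 + dyz**2))
        expected = total / 27
        assert bending_energy(DisplacementField(u)) == pytest.approx(expected, rel=1e-12)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            bending_energy(DisplacementField(np.zeros((3, 2, 4, 4))))


class TestRegistrationLoss:
    def test_perfect_alignment_and_zero_field_gives_zero(self, blob_volume):
        w = LossWeights(sigmas_mm=(0, 1))
        ddf = DisplacementField.zeros(blob_volume.shape)
        assert registration_loss(blob_volume, blob_volume, ddf, w) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_labels_give_one_with_unit_label_weight(self):
        a = label(block((8, 8, 8), (0, 0, 0), (2, 2, 2)))
        b = label(block((8, 8, 8), (6, 6, 6), (8, 8, 8)))
        w = LossWeights(alpha_label=1.0, alpha_def=0.0, sigmas_mm=(0,))
        ddf = DisplacementField.zeros((8, 8, 8))
        assert registration_loss(a, b, ddf, w) == pytest.approx(1.0, abs=1e-6)

    def test_components_sum(self, rng):
        a = label(rng.uniform(0, 1, (6, 6, 6)))
        b = label(rng.uniform(0, 1, (6, 6, 6)))
        u = DisplacementField(rng.normal(size=(3, 6, 6, 6)) * 0.5)
        w = LossWeights(alpha_label=1.0, alpha_def=1.0, sigmas_mm=(0, 2))
        from metareg.core_spatial import warp
        expected = (1 - multiscale_dice(warp(a, u), b, w)) + bending_energy(u)
        assert registration_loss(a, b, u, w) == pytest.approx(expected, rel=1e-9)

    def test_nonnegative(self, rng):
        a = label(rng.uniform(0, 1, (6, 6, 6)))
        b = label(rng.uniform(0, 1, (6, 6, 6)))
        u = DisplacementField(rng.normal(size=(3, 6, 6, 6)))
        assert registration_loss(a, b, u, LossWeights(sigmas_mm=(0, 1))) >= 0
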