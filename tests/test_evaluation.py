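"""TRE/DSC metrics, few-shot curves and regime comparisons."""

import numpy as np
import pytest

from metareg.core_spatial import DisplacementField, LandmarkSet, Volume
from metareg.evaluation import (FewShotCurve, _centroid_ddf, compare_regimes,
                                dsc, evaluate_few_shot, tre, warp_landmarks)
from metareg.losses import LossWeights
from metareg.metalearn import RegistrationMetaProblem
from metareg.network import NetworkConfig, RegistrationNetwork
from metareg.synthetic_data import GeneratorParams, generate_cohort


def ball_mask(grid, centre, r=1.6):
    idx = np.indices(grid, dtype=float)
    d2 = sum((idx[a] - centre[a]) ** 2 for a in range(3))
    return (d2 <= r * r).astype(float)


class TestDSC:
    def test_identical_masks(self):
        m = Volume(ball_mask((8, 8, 8), (4, 4, 4)), is_label=True)
        assert dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = Volume(ball_mask((10, 10, 10), (2, 2, 2)), is_label=True)
        b = Volume(ball_mask((10, 10, 10), (7, 7, 7)), is_label=True)
        assert dsc(a, b) == 0.0

    def test_hand_arithmetic_overlap(self):
        a = np.zeros((10, 10, 10)); a[0:4, 0:5, 0:5] = 1  # |A| = 100
        b = np.zeros((10, 10, 10)); b[0:4, 0:5, 1:5] = 1  # |B| = 80, overlap 80
        # construct |B|=100 overlapping 80: shift one 5x5x4 block by 1
        b = np.zeros((10, 10, 10)); b[0:4, 1:6, 0:5] = 1
        va, vb = Volume(a, is_label=True), Volume(b, is_label=True)
        assert dsc(va, vb) == pytest.approx(2 * 80 / (100 + 100))

    def test_both_empty_warns_and_returns_zero(self):
        z = Volume(np.zeros((4, 4, 4)), is_label=True)
        with pytest.warns(UserWarning, match="empty"):
            assert dsc(z, z) == 0.0


class TestTRE:
    def test_aligned_centroids_give_zero(self):
        m = LandmarkSet([ball_mask((8, 8, 8), (4, 4, 4))])
        assert tre(m, m, 1.0) == 0.0

    def test_single_pair_distance(self):
        a = LandmarkSet([ball_mask((12, 12, 12), (4, 4, 4))])
        b = LandmarkSet([ball_mask((12, 12, 12), (4, 4, 7))])
        assert tre(a, b, 1.0) == pytest.approx(3.0, abs=1e-9)

    def test_rms_of_three_and_four_mm(self):
        a = LandmarkSet([ball_mask((16, 16, 16), (4, 4, 4)),
                         ball_mask((16, 16, 16), (10, 10, 10))])
        b = LandmarkSet([ball_mask((16, 16, 16), (4, 4, 7)),
                         ball_mask((16, 16, 16), (10, 6, 10))])
        # distances 3 and 4 voxels at 1 mm -> sqrt((9+16)/2)
        assert tre(a, b, 1.0) == pytest.approx(np.sqrt(12.5), abs=1e-9)

    def test_spacing_scales_to_mm(self):
        a = LandmarkSet([ball_mask((12, 12, 12), (4, 4, 4))])
        b = LandmarkSet([ball_mask((12, 12, 12), (4, 4, 6))])
        assert tre(a, b, 0.8) == pytest.approx(1.6, abs=1e-9)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tre(LandmarkSet([]), LandmarkSet([]), 1.0)

    def test_invariant_under_consistent_pair_permutation(self, rng):
        masks_a = [ball_mask((12, 12, 12), c) for c in [(3, 3, 3), (8, 8, 8), (5, 9, 4)]]
        masks_b = [ball_mask((12, 12, 12), c) for c in [(4, 3, 3), (8, 9, 8), (5, 9, 6)]]
        perm = [2, 0, 1]
        t1 = tre(LandmarkSet(masks_a), LandmarkSet(masks_b), 1.0)
        t2 = tre(LandmarkSet([masks_a[i] for i in perm]),
                 LandmarkSet([masks_b[i] for i in perm]), 1.0)
        assert t1 == pytest.approx(t2, rel=1e-12)


@pytest.fixture(scope="module")
def tiny_setup():
    params = GeneratorParams(grid_shape=(16, 16, 16))
    _, test = generate_cohort(1, 4, base_seed=11, params=params)
    net = RegistrationNetwork(NetworkConfig(levels=2, base_channels=2, seed=0))
    prob = RegistrationMetaProblem(net, LossWeights(sigmas_mm=(0, 2)),
                                   f_min=2, f_max=4)
    return prob, net, test


class TestFewShotCurve:
    def test_row_structure_and_update_counts(self, tiny_setup):
        prob, net, test = tiny_setup
        curve = evaluate_few_shot(prob, net.init_weights(), test, 2, 4, 1e-3)
        assert curve.f_values == [2, 3, 4]
        assert curve.grad_updates == [0, 1, 2]
        assert curve.tre_mm.shape == (3, 4)

    def test_single_row_when_bounds_equal(self, tiny_setup):
        prob, net, test = tiny_setup
        curve = evaluate_few_shot(prob, net.init_weights(), test, 3, 3, 1e-3)
        assert curve.f_values == [3] and curve.grad_updates == [0]

    def test_deterministic_rerun(self, tiny_setup):
        prob, net, test = tiny_setup
        c1 = evaluate_few_shot(prob, net.init_weights(), test, 2, 4, 1e-3)
        c2 = evaluate_few_shot(prob, net.init_weights(), test, 2, 4, 1e-3)
        np.testing.assert_array_equal(c1.tre_mm, c2.tre_mm)

    def test_spearman_of_monotone_curve(self):
        curve = FewShotCurve([2, 3, 4], [0, 1, 2],
                             np.array([[3.0], [2.0], [1.0]]),
                             np.ones((3, 1)))
        assert curve.spearman_f_vs_tre() == pytest.approx(-1.0)


class TestRegimes:
    def test_no_registration_equals_initial_misalignment(self, tiny_setup):
        prob, net, test = tiny_setup
        rep = compare_regimes(test, prob, None, None, 2, 4, 1e-3,
                              regimes=("no_registration",))
        expected = np.median([
            tre(t.source_landmarks, t.target_landmarks, 1.0) for t in test])
        assert rep.loc["no_registration", "median_tre_mm"] == pytest.approx(expected)

    def test_centroid_alignment_beats_no_registration(self):
        """Translating the gland centroid onto the target's reduces median
        landmark error on default synthetic cohorts."""
        params = GeneratorParams(grid_shape=(16, 16, 16))
        _, test = generate_cohort(1, 12, base_seed=21, params=params)
        net = RegistrationNetwork(NetworkConfig(levels=2, base_channels=2, seed=0))
        prob = RegistrationMetaProblem(net, LossWeights(sigmas_mm=(0,)), 2, 4)
        rep = compare_regimes(test, prob, None, None, 2, 4, 1e-3,
                              regimes=("no_registration", "centroid_alignment"))
        assert (rep.loc["centroid_alignment", "median_tre_mm"]
                <= rep.loc["no_registration", "median_tre_mm"])

    def test_centroid_field_is_constant_shift(self, tiny_setup):
        _, _, test = tiny_setup
        task = test[0]
        ddf = _centroid_ddf(task)
        u0 = ddf.vectors[:, 0, 0, 0]
        assert np.allclose(ddf.vectors, u0[:, None, None, None])
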