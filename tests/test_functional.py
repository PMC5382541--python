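"""Buffering, functional connectivity curves, bias curves and thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from canopyconn import (
    BiasCurve,
    ConnectivityCurve,
    Stratum,
    StratumMask,
    bias_curve,
    buffer_mask,
    connectivity_index,
    functional_curve,
    label_patches,
    peak_bias,
    threshold_distance,
)

from conftest import brute_force_buffer, random_mask


def make_mask(values, pixel_size=1.5, stratum=Stratum.GREEN2D):
    return StratumMask(np.asarray(values, dtype=bool), stratum, pixel_size)


class TestBuffer:
    def test_zero_distance_is_identity(self, rng):
        mask = random_mask(rng, (16, 16))
        assert np.array_equal(buffer_mask(mask, 0.0).values, mask.values)

    def test_full_mask_unchanged(self):
        mask = make_mask(np.ones((8, 8)))
        assert buffer_mask(mask, 37.0).values.all()

    def test_single_pixel_disc_matches_center_distances(self):
        values = np.zeros((9, 9), dtype=bool)
        values[4, 4] = True
        mask = make_mask(values, pixel_size=1.5)
        got = buffer_mask(mask, 3.0).values
        rr, cc = np.indices(values.shape)
        expected = np.hypot(rr - 4, cc - 4) * 1.5 <= 3.0 + 1e-9
        assert np.array_equal(got, expected)
        # the exact-radius ring (2 px = 3.0 m) must be included
        assert got[4, 6] and got[2, 4]
        assert not got[2, 2]  # sqrt(8)*1.5 = 4.24 m

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(8):
            mask = random_mask(rng, (24, 24), density=0.05)
            if not mask.values.any():
                continue
            for d in (1.0, 2.5, 4.0, 7.3):
                assert np.array_equal(
                    buffer_mask(mask, d).values, brute_force_buffer(mask, d)
                )

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            buffer_mask(make_mask(np.ones((2, 2))), -1.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    values=hnp.arrays(bool, (14, 14)),
    d1=st.floats(0, 10),
    d2=st.floats(0, 10),
)
def test_buffer_nesting(values, d1, d2):
    """Buffers grow monotonically: d1 <= d2 implies set inclusion."""
    if not values.any():
        return
    lo, hi = sorted((d1, d2))
    mask = make_mask(values)
    b_lo = buffer_mask(mask, lo).values
    b_hi = buffer_mask(mask, hi).values
    assert not (b_lo & ~b_hi).any()


class TestCurve:
    def test_full_cover_input_terminates_immediately(self):
        curve = functional_curve(make_mask(np.ones((6, 6))))
        assert list(curve.distances_m) == [0.0]
        assert list(curve.ci_values) == [0.0]
        assert curve.terminated_full_cover

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            functional_curve(make_mask(np.zeros((6, 6))))

    def test_first_point_is_structural_ci(self, rng):
        mask = random_mask(rng, (24, 24), density=0.2)
        curve = functional_curve(mask)
        assert curve.ci_values[0] == connectivity_index(label_patches(mask, 8))

    def test_two_distant_pixels_match_stepwise_oracle(self):
        """Two isolated pixels 10 px apart: CI at every sampled distance
        must equal the CI of the brute-force-buffered mask."""
        values = np.zeros((32, 32), dtype=bool)
        values[15, 10] = True
        values[15, 20] = True
        mask = make_mask(values, pixel_size=1.5)
        curve = functional_curve(mask, step_m=1.0)
        for d, ci in zip(curve.distances_m, curve.ci_values):
            oracle_mask = make_mask(brute_force_buffer(mask, d))
            assert ci == connectivity_index(label_patches(oracle_mask, 8))
        assert curve.terminated_full_cover
        assert curve.ci_values[-1] == 0.0
        # the two patches merge once buffers span half the 15 m gap:
        # first 1 m step covering the midpoint pixel is d = 8
        assert label_patches(buffer_mask(mask, 7.0), 8).n_patches == 2
        assert label_patches(buffer_mask(mask, 8.0), 8).n_patches == 1

    def test_curve_monotone_on_random_masks(self, rng):
        for _ in range(5):
            mask = random_mask(rng, (24, 24), density=0.1)
            if not mask.values.any():
                continue
            curve = functional_curve(mask)
            assert np.all(np.diff(curve.ci_values) <= 1e-12)
            assert curve.terminated_full_cover

    def test_max_distance_cutoff_warns(self):
        values = np.zeros((40, 40), dtype=bool)
        values[0, 0] = True
        mask = make_mask(values)
        with pytest.warns(UserWarning):
            curve = functional_curve(mask, max_distance_m=3.0)
        assert not curve.terminated_full_cover
        assert curve.ci_values[-1] > 0


class TestThresholdDistance:
    def curve(self, ds, cis):
        return ConnectivityCurve(
            Stratum.GRASS,
            np.asarray(ds, float),
            np.asarray(cis, float),
            terminated_full_cover=cis[-1] == 0.0,
        )

    def test_already_below_threshold_at_zero(self):
        assert threshold_distance(self.curve([0.0], [0.0])) == 0.0
        assert threshold_distance(self.curve([0, 1, 2], [0.10, 0.05, 0.0])) == 0.0

    def test_first_strict_crossing(self):
        c = self.curve([0, 1, 2, 3], [0.9, 0.3, 0.14, 0.0])
        assert threshold_distance(c, 0.15) == 2.0

    def test_threshold_is_strict(self):
        c = self.curve([0, 1, 2], [0.9, 0.15, 0.0])
        assert threshold_distance(c, 0.15) == 2.0

    def test_never_attained_returns_none(self):
        c = ConnectivityCurve(
            Stratum.TREE, np.array([0.0, 1.0]), np.array([0.9, 0.8]), False
        )
        assert threshold_distance(c, 0.15) is None


class TestBias:
    def curve(self, layer, cis):
        cis = np.asarray(cis, float)
        return ConnectivityCurve(
            layer, np.arange(len(cis), dtype=float), cis, cis[-1] == 0.0
        )

    def test_identical_curves_zero_delta(self):
        g = self.curve(Stratum.GREEN2D, [0.8, 0.4, 0.0])
        s = self.curve(Stratum.GRASS, [0.8, 0.4, 0.0])
        assert np.all(bias_curve(s, g).delta_ci == 0.0)

    def test_shorter_curve_extended_with_zeros(self):
        g = self.curve(Stratum.GREEN2D, [0.6, 0.0])
        s = self.curve(Stratum.TREE, [0.9, 0.5, 0.2, 0.0])
        b = bias_curve(s, g)
        assert list(b.distances_m) == [0.0, 1.0, 2.0, 3.0]
        assert b.delta_ci[2] == pytest.approx(0.2)
        assert b.delta_ci[3] == 0.0

    def test_mismatched_steps_rejected(self):
        g = ConnectivityCurve(
            Stratum.GREEN2D, np.array([0.0, 2.0]), np.array([0.5, 0.0]), True
        )
        s = self.curve(Stratum.GRASS, [0.9, 0.4, 0.0])
        with pytest.raises(ValueError):
            bias_curve(s, g)

    def test_peak_bias_tiebreak_smallest_distance(self):
        b = BiasCurve(Stratum.GRASS, np.array([0.0, 1.0, 2.0]), np.zeros(3))
        assert peak_bias(b) == (0.0, 0.0)
        b2 = BiasCurve(
            Stratum.GRASS, np.array([0.0, 5.0, 9.0]), np.array([0.1, 0.4, 0.2])
        )
        assert peak_bias(b2) == (5.0, pytest.approx(0.4))
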