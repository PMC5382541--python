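"""Patch labeling and the four structural connectivity metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from canopyconn import (
    Stratum,
    StratumMask,
    connectivity_index,
    label_patches,
    landscape_proportion,
    largest_patch_index,
    small_patch_density,
    structural_summary,
)

from conftest import mc_ci_estimate, random_mask


def make_mask(values, pixel_size=1.5):
    return StratumMask(np.asarray(values, dtype=bool), Stratum.GREEN2D, pixel_size)


class TestLabeling:
    def test_diagonal_pixels_connectivity_choice(self):
        mask = make_mask([[1, 0], [0, 1]])
        assert label_patches(mask, 8).n_patches == 1
        assert label_patches(mask, 4).n_patches == 2

    def test_empty_mask_has_no_patches(self):
        lab = label_patches(make_mask(np.zeros((5, 5))))
        assert lab.n_patches == 0
        assert not lab.labels.any()

    def test_labels_dense_and_row_major_ordered(self, rng):
        mask = random_mask(rng, (32, 32), density=0.25)
        lab = label_patches(mask, 4)
        flat = lab.labels.ravel()
        firsts = [np.flatnonzero(flat == k)[0] for k in range(1, lab.n_patches + 1)]
        assert firsts == sorted(firsts)
        assert set(np.unique(lab.labels)) == set(range(lab.n_patches + 1))

    def test_areas_sum_to_vegetated_area(self, rng):
        mask = random_mask(rng, (20, 20), density=0.4)
        lab = label_patches(mask)
        assert lab.patch_areas_m2.sum() == pytest.approx(
            mask.values.sum() * mask.pixel_area_m2
        )
        assert lab.landscape_area_m2 == pytest.approx(400 * 2.25)

    def test_bad_neighborhood_rejected(self):
        with pytest.raises(ValueError):
            label_patches(make_mask(np.ones((2, 2))), 6)


class TestMetrics:
    def test_landscape_proportion_direct_ratio(self):
        values = np.zeros((10, 10), dtype=bool)
        values.ravel()[:30] = True
        lab = label_patches(make_mask(values))
        assert landscape_proportion(lab) == pytest.approx(0.30)

    @pytest.mark.parametrize(
        "n_pixels,expected_count", [(13, 1), (14, 0)]  # 29.25 vs 31.5 m^2 at 1.5 m
    )
    def test_small_patch_threshold_is_strict_at_30m2(self, n_pixels, expected_count):
        values = np.zeros((40, 40), dtype=bool)
        values[0, :n_pixels] = True
        lab = label_patches(make_mask(values))
        hectares = lab.landscape_area_m2 / 1e4
        assert small_patch_density(lab) == pytest.approx(expected_count / hectares)

    def test_largest_patch_index_percent(self):
        values = np.zeros((10, 10), dtype=bool)
        values[0, :] = True   # 10 px row patch
        values[2:5, :] = True  # 30 px block
        values[6:8, :] = True  # 20 px block
        lab = label_patches(make_mask(values))
        assert largest_patch_index(lab) == pytest.approx(30.0)

    def test_ci_analytic_cases(self):
        full = label_patches(make_mask(np.ones((8, 8))))
        assert connectivity_index(full) == 0.0
        empty = label_patches(make_mask(np.zeros((8, 8))))
        assert connectivity_index(empty) == 1.0

    def test_ci_two_half_landscape_patches(self):
        # fully vegetated landscape split into two 4-disconnected halves
        values = np.zeros((10, 11), dtype=bool)
        values[:, :5] = True
        values[:, 6:] = True
        lab = label_patches(make_mask(values), 4)
        # two patches of 50 px each in a 110 px landscape
        assert connectivity_index(lab) == pytest.approx(1 - 2 * (50 / 110) ** 2)

    def test_ci_30_20_10_patches_of_100(self):
        values = np.zeros((10, 10), dtype=bool)
        values[0:3, :] = True  # 30 px
        values[4:6, :] = True  # 20 px
        values[7, :] = True    # 10 px
        lab = label_patches(make_mask(values))
        assert connectivity_index(lab) == pytest.approx(0.86)
        assert largest_patch_index(lab) == pytest.approx(30.0)

    def test_ci_matches_monte_carlo_pair_sampling(self, rng):
        """CI is by definition the probability two random pixels do not
        share a patch; check against direct pair sampling."""
        for _ in range(5):
            mask = random_mask(rng, (48, 48), density=rng.uniform(0.1, 0.6))
            lab = label_patches(mask, int(rng.choice([4, 8])))
            ci = connectivity_index(lab)
            p_hat, se = mc_ci_estimate(lab.labels, rng)
            assert abs(ci - p_hat) <= 3 * se + 1e-12

    def test_summary_trivial_landscapes(self):
        full = structural_summary(make_mask(np.ones((6, 6))))
        assert (
            full.landscape_proportion,
            full.small_patch_density,
            full.largest_patch_index,
            full.ci,
        ) == (1.0, 0.0, 100.0, 0.0)
        empty = structural_summary(make_mask(np.zeros((6, 6))))
        assert (
            empty.landscape_proportion,
            empty.small_patch_density,
            empty.largest_patch_index,
            empty.ci,
        ) == (0.0, 0.0, 0.0, 1.0)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    values=hnp.arrays(bool, (12, 12)),
    pixel=st.integers(0, 143),
    neighborhood=st.sampled_from([4, 8]),
)
def test_adding_a_vegetated_pixel_never_increases_ci(values, pixel, neighborhood):
    """Vegetating any background pixel grows or merges patches, so the
    division index can only drop."""
    mask = make_mask(values)
    grown = values.copy()
    grown.ravel()[pixel] = True
    ci_before = connectivity_index(label_patches(mask, neighborhood))
    ci_after = connectivity_index(label_patches(make_mask(grown), neighborhood))
    assert ci_after <= ci_before + 1e-12


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    values=hnp.arrays(bool, (12, 12)),
    extra=hnp.arrays(bool, (12, 12)),
    neighborhood=st.sampled_from([4, 8]),
)
def test_mask_inclusion_implies_ci_dominance(values, extra, neighborhood):
    """If M1 is a subset of M2 then CI(M2) <= CI(M1): a superset layer
    (the flat 2D view) always looks at least as connected."""
    m1 = make_mask(values)
    m2 = make_mask(values | extra)
    ci1 = connectivity_index(label_patches(m1, neighborhood))
    ci2 = connectivity_index(label_patches(m2, neighborhood))
    assert ci2 <= ci1 + 1e-12
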