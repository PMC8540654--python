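from collections import deque
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylloplane import (
    bc_load,
    category_fold_change,
    coincidence_particles,
    detect_particles,
    simulate_zstack_pair,
    threshold_channel,
)


def flood_fill_components(mask: np.ndarray, connectivity: int) -> int:
    """Independent component counter: breadth-first flood fill."""
    offsets = [
        o
        for o in product((-1, 0, 1), repeat=3)
        if o != (0, 0, 0)
        and {6: sum(map(abs, o)) == 1, 18: sum(map(abs, o)) <= 2, 26: True}[connectivity]
    ]
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        count += 1
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            for o in offsets:
                w = tuple(np.add(v, o))
                if all(0 <= w[i] < mask.shape[i] for i in range(3)):
                    if mask[w] and not seen[w]:
                        seen[w] = True
                        queue.append(w)
    return count


class TestThreshold:
    def test_single_hot_voxel(self):
        channel = np.zeros((5, 5, 5))
        channel[2, 3, 1] = 1000.0
        mask = threshold_channel(channel)
        assert mask.sum() == 1 and mask[2, 3, 1]

    def test_constant_image_saturates_mask(self):
        # degenerate: every voxel equals the maximum, so every voxel clears
        # a threshold set 0.1% below it
        mask = threshold_channel(np.full((4, 4, 4), 7.0))
        assert mask.all()

    def test_all_zero_channel_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            mask = threshold_channel(np.zeros((3, 3, 3)))
        assert not mask.any()

    def test_matches_exhaustive_voxel_scan(self):
        rng = np.random.default_rng(8)
        channel = rng.integers(0, 256, size=(12, 12, 6)).astype(float)
        mask = threshold_channel(channel, fraction=0.001)
        cut = 0.999 * channel.max()
        expected = {tuple(v) for v in np.argwhere(channel > cut)}
        assert {tuple(v) for v in np.argwhere(mask)} == expected
        # with max 255 the cut of 254.745 retains exactly the 255 voxels
        assert expected == {tuple(v) for v in np.argwhere(channel == 255)}

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_mask_grows_with_fraction_and_ignores_scale(self, seed):
        rng = np.random.default_rng(seed)
        channel = rng.gamma(2.0, size=(8, 8, 4))
        small = threshold_channel(channel, 0.01)
        large = threshold_channel(channel, 0.2)
        assert (small <= large).all()  # monotone in fraction
        np.testing.assert_array_equal(small, threshold_channel(channel * 37.5, 0.01))


class TestCoincidence:
    def test_empty_intersection_means_no_particles(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.ones((4, 4, 4), dtype=bool)
        assert coincidence_particles(a, b).count == 0

    def test_identical_single_voxel_masks(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[1, 2, 3] = True
        ps = coincidence_particles(a, a.copy())
        assert ps.count == 1
        assert len(ps.voxels[0]) == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            coincidence_particles(np.zeros((3, 3, 3), bool), np.zeros((4, 3, 3), bool))

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_component_count_matches_flood_fill(self, connectivity):
        rng = np.random.default_rng(3)
        for _ in range(5):
            mask = rng.random((10, 10, 10)) < 0.15
            ps = coincidence_particles(mask, np.ones_like(mask), connectivity)
            assert ps.count == flood_fill_components(mask, connectivity)

    def test_connectivity_ordering_on_diagonal_touch(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True  # corner contact only
        assert coincidence_particles(mask, mask, 26).count == 1
        assert coincidence_particles(mask, mask, 6).count == 2


class TestDetectorOnSyntheticStacks:
    def test_planted_recovery_and_confounder_rejection(self):
        pair, truth = simulate_zstack_pair(10, 5, seed=42, snr=5.0)
        ps = detect_particles(pair)
        assert ps.count == truth.n_particles
        detected = {tuple(np.round(c).astype(int)) for c in ps.centroids}
        assert detected == {tuple(c) for c in truth.particle_centers}

    def test_confounders_alone_yield_zero(self):
        pair, _ = simulate_zstack_pair(0, 8, shape=(48, 48, 24), seed=13)
        assert detect_particles(pair).count == 0

    def test_joint_scale_invariance_of_count(self):
        pair, truth = simulate_zstack_pair(6, 3, seed=5)
        base = detect_particles(pair).count
        pair.channel_shg *= 123.0
        pair.channel_af *= 0.007
        assert detect_particles(pair).count == base == truth.n_particles


class TestBcLoad:
    def test_zero_counts_zero_load(self):
        rec = bc_load([0, 0, 0], 1e6, 8.0, 2.0)
        assert rec.load_particles_per_g == 0.0

    def test_hand_arithmetic_example(self):
        # mean 10 particles in 425.1 x 425.1 x 35.1 um^3, 8 mL wash, 2 g leaf
        vol = 425.1 * 425.1 * 35.1
        rec = bc_load([10, 10, 10, 10, 10], vol, 8.0, 2.0)
        assert rec.load_particles_per_g == pytest.approx(10 / vol * 8e12 / 2, rel=1e-12)
        assert rec.load_particles_per_g == pytest.approx(6.305e6, rel=1e-3)

    def test_load_halves_when_mass_doubles(self):
        a = bc_load([3, 5], 1e6, 8.0, 1.0).load_particles_per_g
        b = bc_load([3, 5], 1e6, 8.0, 2.0).load_particles_per_g
        assert a == pytest.approx(2 * b)

    @pytest.mark.parametrize("bad", [([], 1e6, 8, 2), ([1], 0, 8, 2), ([1], 1e6, 8, 0)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            bc_load(*bad)


class TestFoldChange:
    CATEGORY_MAP = {"HGa": "bcM", "HGb": "bcM", "HKa": "bcH", "HKb": "bcH", "DM": "bcL", "DW": "bcL"}
    SITE_LOADS = {"HGa": 1.9, "HGb": 1.7, "HKa": 4.1, "HKb": 4.4, "DM": 0.6, "DW": 0.7}

    def test_field_site_means_fall_in_reported_fold_range(self):
        ratios = category_fold_change(self.SITE_LOADS, self.CATEGORY_MAP)
        assert ratios[("bcH", "bcL")] == pytest.approx(4.25 / 0.65, rel=1e-12)
        assert ratios[("bcM", "bcL")] == pytest.approx(1.8 / 0.65, rel=1e-12)
        assert 2 <= ratios[("bcM", "bcL")] <= ratios[("bcH", "bcL")] <= 7

    def test_equal_category_means_give_unit_ratio(self):
        ratios = category_fold_change(
            {"a": 2.0, "b": 2.0}, {"a": "bcL", "b": "bcH"}
        )
        assert ratios[("bcH", "bcL")] == pytest.approx(1.0)

    def test_zero_denominator_category_raises(self):
        with pytest.raises(ZeroDivisionError):
            category_fold_change({"a": 0.0, "b": 1.0}, {"a": "bcL", "b": "bcH"})
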