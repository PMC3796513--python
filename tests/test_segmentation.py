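"""Arm segmentation: component labelling, side assignment, voxel statistics."""

import numpy as np
import pytest

import limbpet as lp
from limbpet.errors import InvariantError, SegmentationError


def _flood_fill_components(foreground):
    """Independent brute-force 26-connectivity labelling (BFS) for small grids."""
    from collections import deque

    labels = np.zeros(foreground.shape, dtype=int)
    current = 0
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for idx in np.argwhere(foreground):
        idx = tuple(idx)
        if labels[idx]:
            continue
        current += 1
        queue = deque([idx])
        labels[idx] = current
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offsets:
                nxt = (x + dx, y + dy, z + dz)
                if all(0 <= nxt[i] < foreground.shape[i] for i in range(3)) and \
                        foreground[nxt] and not labels[nxt]:
                    labels[nxt] = current
                    queue.append(nxt)
    return labels, current


def test_noiseless_phantom_recovered_exactly(small_null_phantom):
    """With a threshold midway between air and tissue, recovered masks equal
    the planted cylinder masks voxel for voxel (Jaccard = 1)."""
    spec, (_, transmission, truth) = small_null_phantom
    seg = lp.segment_arms(transmission, density_threshold=0.5)
    np.testing.assert_array_equal(seg.left_mask, truth.left_mask)
    np.testing.assert_array_equal(seg.right_mask, truth.right_mask)


def test_otsu_default_threshold_recovers_phantom(small_null_phantom):
    spec, (_, transmission, truth) = small_null_phantom
    seg = lp.segment_arms(transmission)
    assert spec.air_density < seg.density_threshold < spec.tissue_density
    np.testing.assert_array_equal(seg.left_mask | seg.right_mask,
                                  truth.left_mask | truth.right_mask)


def test_side_assignment_by_axis0_centroid(small_null_phantom):
    spec, (_, transmission, _) = small_null_phantom
    seg = lp.segment_arms(transmission, density_threshold=0.5)
    assert seg.left_centroid[0] < seg.right_centroid[0]
    assert seg.component_sizes["left"] == seg.left_mask.sum()


def test_small_speck_excluded_two_arms_kept():
    """A third dense speck of 50 voxels (< min component size 100) is not
    mistaken for a limb; cross-checked against brute-force labelling."""
    spec = lp.PhantomSpec(dims=(64, 32, 32), arm_radius_mm=10.0,
                          arm_separation_mm=60.0, seed=2)
    _, transmission, truth = lp.generate_phantom(spec)
    data = transmission.data.copy()
    data[30:35, 2:7, 2:4] = spec.tissue_density  # 5*5*2 = 50 voxels
    speckled = transmission.with_data(data)
    labels, n = _flood_fill_components(data > 0.5)
    sizes = sorted(np.bincount(labels.ravel())[1:], reverse=True)
    assert n == 3 and sizes[2] == 50  # oracle confirms the layout
    seg = lp.segment_arms(speckled, density_threshold=0.5)
    np.testing.assert_array_equal(seg.left_mask, truth.left_mask)
    np.testing.assert_array_equal(seg.right_mask, truth.right_mask)


def test_matches_brute_force_labelling():
    """Recovered arm masks equal the two largest brute-force components."""
    spec = lp.PhantomSpec(dims=(40, 12, 24), arm_radius_mm=8.0,
                          arm_separation_mm=40.0, seed=9)
    _, transmission, _ = lp.generate_phantom(spec)
    labels, n = _flood_fill_components(transmission.data > 0.5)
    assert n == 2
    seg = lp.segment_arms(transmission, density_threshold=0.5)
    oracle_union = labels > 0
    np.testing.assert_array_equal(seg.left_mask | seg.right_mask, oracle_union)


def test_all_air_volume_fails():
    flat = lp.VoxelVolume(np.zeros((16, 16, 16)), (2, 2, 2), units="density")
    with pytest.raises(SegmentationError):
        lp.segment_arms(flat)


def test_single_component_fails():
    data = np.zeros((16, 16, 16))
    data[4:12, 4:12, 4:12] = 1.0
    vol = lp.VoxelVolume(data, (2, 2, 2), units="density")
    with pytest.raises(SegmentationError):
        lp.segment_arms(vol, density_threshold=0.5)


def test_seeded_mode_and_background_seed(small_null_phantom):
    spec, (_, transmission, truth) = small_null_phantom
    left_seed = tuple(np.argwhere(truth.left_mask)[0])
    right_seed = tuple(np.argwhere(truth.right_mask)[0])
    seg = lp.segment_arms(transmission, density_threshold=0.5,
                          seeds=(right_seed, left_seed))  # order must not matter
    np.testing.assert_array_equal(seg.left_mask, truth.left_mask)
    with pytest.raises(SegmentationError):
        lp.segment_arms(transmission, density_threshold=0.5,
                        seeds=((0, 0, 0), left_seed))


def test_wrong_units_rejected(small_null_phantom):
    _, (emission, _, _) = small_null_phantom
    with pytest.raises(InvariantError):
        lp.segment_arms(emission)


class TestArmVoxelStats:
    def test_constant_region(self):
        vol = lp.VoxelVolume(np.full((10, 10, 10), 5.0), (1, 1, 1))
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[:10, :10, :10] = True
        n, mean, sd = lp.arm_voxel_stats(vol, mask)
        assert (n, mean, sd) == (1000, 5.0, 0.0)

    def test_hand_computed_sample_sd(self):
        """Values {1,2,3,4}: mean 2.5, sample SD sqrt(5/3) ~ 1.2910."""
        data = np.zeros((4, 1, 1))
        data[:, 0, 0] = [1, 2, 3, 4]
        vol = lp.VoxelVolume(data, (1, 1, 1))
        mask = np.ones((4, 1, 1), dtype=bool)
        n, mean, sd = lp.arm_voxel_stats(vol, mask)
        assert n == 4
        assert mean == pytest.approx(2.5)
        assert sd == pytest.approx(1.2909944487, abs=1e-9)

    def test_constructed_reference_moments(self):
        """A volume built to have mean 2086 and sample SD 1371 (the
        magnitudes of a real unaffected-arm reference) reproduces exactly."""
        n = 11674  # even count near a real examined-voxel number
        half = np.full(n // 2, 1.0)
        spread = 1371 * np.sqrt((n - 1) / n)
        values = 2086 + spread * np.concatenate([half, -half])
        data = values.reshape((n // 2, 2, 1))
        vol = lp.VoxelVolume(data, (1, 1, 1))
        mask = np.ones(data.shape, dtype=bool)
        nn, mean, sd = lp.arm_voxel_stats(vol, mask)
        assert mean == pytest.approx(2086.0, abs=1e-9)
        assert sd == pytest.approx(1371.0, abs=1e-6)

    def test_degenerate_masks(self, constant_volume):
        empty = np.zeros(constant_volume.shape, dtype=bool)
        with pytest.raises(InvariantError):
            lp.arm_voxel_stats(constant_volume, empty)
        single = empty.copy()
        single[0, 0, 0] = True
        with pytest.raises(InvariantError):
            lp.arm_voxel_stats(constant_volume, single)
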