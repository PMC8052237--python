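import numpy as np
import pytest

from rhinoflow.airspace import (AirspaceDomain, HUVolume, SegmentationError,
                                block_nostril, detect_tip, extract_airspace,
                                grow_airway, place_probes, threshold_air)
from rhinoflow.phantom import build_phantom_truth

from conftest import study_spec


class TestThreshold:
    @pytest.mark.parametrize("value,expected", [
        (-1000.0, True),   # air
        (0.0, False),      # soft tissue
        (-460.0, True),    # the threshold itself counts as air (inclusive)
    ])
    def test_boundary_rule(self, value, expected):
        vol = HUVolume(np.full((3, 3, 3), value), spacing=1.0)
        assert threshold_air(vol).all() == expected

    def test_nonfinite_values_rejected_with_count(self):
        v = np.zeros((3, 3, 3))
        v[0, 0, 0] = np.nan
        v[1, 1, 1] = np.inf
        with pytest.raises(ValueError, match="2 non-finite"):
            threshold_air(HUVolume(v, 1.0))

    def test_deterministic_on_phantom(self, truth48):
        once = threshold_air(truth48.volume)
        assert np.array_equal(once, threshold_air(truth48.volume))


class TestDetectTip:
    def test_phantom_tip_within_two_voxels(self, truth48):
        air = threshold_air(truth48.volume)
        tip = detect_tip(air)
        assert np.linalg.norm(np.subtract(tip, truth48.tip_vox)) <= 2.0

    def test_all_air_volume_raises(self):
        with pytest.raises(SegmentationError):
            detect_tip(np.ones((10, 10, 10), dtype=bool))

    def test_translation_equivariance(self, truth48):
        air = threshold_air(truth48.volume)
        tip = detect_tip(air)
        k = 3
        shifted = np.zeros_like(air)
        shifted[k:] = air[:-k]
        shifted[:k] = air[0]          # extend the exterior air anteriorly
        tip2 = detect_tip(shifted)
        assert tip2 == (tip[0] + k, tip[1], tip[2])


class TestPlaceProbes:
    def test_smallest_sphere_is_one_voxel_ball(self):
        air = np.ones((21, 21, 21), dtype=bool)
        dom = place_probes(air, (10, 10, 10), spacing=1.0, sphere_diam_mm=2.0,
                           cuboid_dims_mm=(3, 3, 3))
        ball = dom.sphere_mask()
        assert ball.sum() == 7          # centre + six face neighbours
        assert ball[10, 10, 10] and ball[9, 10, 10] and ball[10, 11, 10]

    def test_cuboid_inside_constructed_cavity(self, truth48, domain48):
        o, e = domain48.cuboid_origin_vox, domain48.cuboid_dims_vox
        cav = truth48.cavity_box
        for a in range(3):
            assert cav[a].start <= o[a] and o[a] + e[a] <= cav[a].stop

    def test_sphere_larger_than_grid_raises(self, truth48):
        air = threshold_air(truth48.volume)
        with pytest.raises(SegmentationError, match="axis"):
            place_probes(air, (24, 24, 24), spacing=truth48.spec.spacing,
                         sphere_diam_mm=1000.0,
                         cuboid_dims_mm=truth48.spec.cuboid_dims_mm)


class TestGrowAirway:
    def test_disconnected_blob_removed(self, truth48):
        spec = truth48.spec
        vol = truth48.volume.values.copy()
        vol[2:6, 2:6, 2:6] = spec.hu_air          # isolated air pocket
        dom = extract_airspace(HUVolume(vol, spec.spacing),
                               sphere_diam_mm=spec.sphere_diam_mm,
                               cuboid_dims_mm=spec.cuboid_dims_mm)
        assert not dom.air_mask[2:6, 2:6, 2:6].any()
        assert dom.air_mask.sum() == truth48.lumen.sum()

    def test_fully_connected_air_is_identity(self, domain48, truth48):
        assert np.array_equal(domain48.air_mask, truth48.lumen)
        again = grow_airway(domain48)
        assert np.array_equal(again.air_mask, domain48.air_mask)

    def test_grown_mask_subset_of_threshold(self, truth48, domain48):
        air = threshold_air(truth48.volume)
        assert not (domain48.air_mask & ~air).any()

    def test_seed_not_air_raises(self, truth48):
        dom = AirspaceDomain(
            air_mask=truth48.lumen, tip_vox=truth48.tip_vox,
            sphere_diam_mm=truth48.spec.sphere_diam_mm,
            cuboid_origin_vox=(1, 1, 1), cuboid_dims_vox=(2, 2, 2),
            spacing=truth48.spec.spacing)
        with pytest.raises(SegmentationError, match="seed is not air"):
            grow_airway(dom)


class TestBlockNostril:
    def test_block_none_is_identity(self, domain48):
        assert block_nostril(domain48, "none") is domain48

    def test_blocking_removes_only_plug_voxels(self, domain48, truth48):
        blocked = block_nostril(domain48, "right")
        diff = domain48.air_mask & ~blocked.air_mask
        assert diff.any()
        # the plug lies inside the right channel, in a thin AP range
        assert diff[:, :, :domain48.air_mask.shape[2] // 2].sum() == 0
        aps = np.unique(np.argwhere(diff)[:, 0])
        assert len(aps) <= 3

    def test_blocking_both_sides_raises(self, domain48):
        one = block_nostril(domain48, "right")
        with pytest.raises(SegmentationError, match="no airway path"):
            block_nostril(one, "left")
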