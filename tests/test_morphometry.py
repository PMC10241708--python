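"""Minimal Feret diameter, perivascular bands, and image-level metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_convex_points, sweep_min_width
from vesselquant.vessel_morphometry import (
    UndefinedMetric,
    _pixel_corner_points,
    fraction_covered,
    median_vessel_diameter,
    min_feret,
    min_width_convex,
    perivascular_intensity,
    perivascular_rings,
    stromal_metrics,
    vessel_density,
)


def _disc_mask(shape, center, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestMinFeret:
    def test_axis_aligned_rectangle(self):
        m = np.zeros((60, 60), dtype=bool)
        m[10:50, 10:26] = True  # 40 x 16 px
        assert min_feret(m, 4.0) == pytest.approx(4.0)

    def test_disc_diameter(self):
        m = _disc_mask((100, 100), (50, 50), 20)
        assert min_feret(m, 4.0) == pytest.approx(10.0, abs=0.25)

    def test_single_pixel_is_one_pixel_wide(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        assert min_feret(m, 1.0) == pytest.approx(1.0)

    def test_empty_footprint_raises(self):
        with pytest.raises(ValueError, match="empty"):
            min_feret(np.zeros((4, 4), dtype=bool), 4.0)

    def test_rotated_rectangle_near_short_side(self):
        # 40 x 16 px rectangle rotated 30 deg, rasterized
        theta = np.deg2rad(30)
        rr, cc = np.mgrid[0:80, 0:80]
        u = np.cos(theta) * (cc - 40) + np.sin(theta) * (rr - 40)
        v = -np.sin(theta) * (cc - 40) + np.cos(theta) * (rr - 40)
        # 16 px across = pixel centers within +/-7.5 of the axis
        m = (np.abs(u) <= 19.5) & (np.abs(v) <= 7.5)
        assert min_feret(m, 4.0) == pytest.approx(4.0, abs=0.3)

    def test_matches_projection_sweep_on_hull_points(self, rng):
        for _ in range(30):
            pts = random_convex_points(rng)
            rc = min_width_convex(pts)
            sweep = sweep_min_width(pts)
            assert sweep >= rc - 1e-9  # sweep can only overestimate
            assert sweep - rc < 1e-6

    def test_matches_projection_sweep_on_rasters(self, rng):
        for _ in range(10):
            radius = rng.integers(6, 20)
            m = _disc_mask((60, 60), (30, 30), radius)
            corners = _pixel_corner_points(np.argwhere(m))
            assert min_width_convex(corners) == pytest.approx(
                sweep_min_width(corners), abs=1.0
            )

    @given(st.floats(0, np.pi))
    @settings(max_examples=20, deadline=None)
    def test_rotation_invariance_of_rasterized_square(self, theta):
        rr, cc = np.mgrid[0:64, 0:64]
        u = np.cos(theta) * (cc - 32) + np.sin(theta) * (rr - 32)
        v = -np.sin(theta) * (cc - 32) + np.cos(theta) * (rr - 32)
        m = (np.abs(u) <= 10) & (np.abs(v) <= 10)
        # 20 px side at resolution 1: within pixel-quantization tolerance
        assert min_feret(m, 1.0) == pytest.approx(20.0, abs=2.0)


class TestDensityAndMedian:
    def test_density_arithmetic(self):
        # 1000x1000 px at 4 px/um is 0.0625 mm^2
        assert vessel_density(5, 0.0625) == pytest.approx(80.0)
        assert vessel_density(0, 0.0625) == 0.0

    def test_density_with_exclusion_halved_area(self):
        assert vessel_density(12, 0.03125) == pytest.approx(384.0)

    def test_density_scales_inversely_with_area(self):
        assert vessel_density(7, 0.02) == pytest.approx(2 * vessel_density(7, 0.04))

    def test_density_rejects_nonpositive_area(self):
        with pytest.raises(ValueError):
            vessel_density(3, 0.0)

    @pytest.mark.parametrize(
        "diameters,expected",
        [([4, 6, 20], 6.0), ([4, 6, 10, 20], 8.0)],
    )
    def test_median_diameter(self, diameters, expected):
        assert median_vessel_diameter(diameters) == expected

    def test_median_of_empty_set_flagged(self):
        with pytest.raises(UndefinedMetric):
            median_vessel_diameter([])


class TestPerivascularRings:
    def test_annulus_area_close_to_analytic(self):
        labels = _disc_mask((200, 200), (100, 100), 30).astype(np.int32)
        rings = perivascular_rings(labels, ring_distance_px=10)
        area = (rings == 1).sum()
        analytic = np.pi * ((30 + 10) ** 2 - 30**2)
        assert abs(area - analytic) / analytic < 0.02

    def test_rings_disjoint_from_footprints_and_nearest_assigned(self):
        labels = np.zeros((80, 120), dtype=np.int32)
        labels[_disc_mask((80, 120), (40, 30), 10)] = 1
        labels[_disc_mask((80, 120), (40, 44), 10)] = 2  # 4 px apart
        rings = perivascular_rings(labels, 10)
        assert not np.any((rings > 0) & (labels > 0))
        # each ring pixel is within 10 px of its own vessel
        from scipy import ndimage

        for lab in (1, 2):
            d = ndimage.distance_transform_edt(labels != lab)
            sel = rings == lab
            assert np.all(d[sel] <= 10)
            assert np.all(d[sel] > 0)

    def test_border_vessel_ring_clipped(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[_disc_mask((40, 40), (3, 3), 5)] = 1
        rings = perivascular_rings(labels, 10)
        assert (rings == 1).sum() > 0  # exists but clipped to bounds


class TestIntensityAndCoverage:
    def test_uniform_od_gives_that_median(self):
        labels = _disc_mask((60, 60), (30, 30), 8).astype(np.int32)
        rings = perivascular_rings(labels, 10)
        per_vessel, pvi = perivascular_intensity(rings, np.full((60, 60), 0.7))
        assert per_vessel[1] == pytest.approx(0.7)
        assert pvi == pytest.approx(0.7)

    def test_zero_od_gives_zero_pvi(self):
        labels = _disc_mask((60, 60), (30, 30), 8).astype(np.int32)
        rings = perivascular_rings(labels, 10)
        _, pvi = perivascular_intensity(rings, np.zeros((60, 60)))
        assert pvi == 0.0

    def test_fraction_covered_examples(self):
        assert fraction_covered([0.1, 0.2, 0.8, 0.9], 0.5) == 0.5
        assert fraction_covered([0.8, 0.9], 0.5) == 1.0
        with pytest.raises(UndefinedMetric):
            fraction_covered([], 0.5)

    def test_self_median_cutoff_gives_half(self, rng):
        vals = rng.uniform(0, 1, 101)  # distinct values, odd n
        fcv = fraction_covered(vals, float(np.median(vals)))
        assert abs(fcv - 0.5) <= 1 / len(vals)


class TestStromalMetrics:
    def test_zero_od_everywhere(self):
        area, med = stromal_metrics(
            np.zeros((50, 50)), np.zeros((50, 50), dtype=bool), 4.0
        )
        assert area == 0.0 and med is None

    def test_half_image_uniform_od(self):
        od = np.zeros((1000, 1000))
        od[:500, :] = 0.6
        area, med = stromal_metrics(
            od, np.zeros_like(od, dtype=bool), 4.0, stroma_threshold_od=0.3
        )
        assert area == pytest.approx(0.03125)
        assert med == pytest.approx(0.6)

    def test_median_matches_brute_force_sort(self, rng):
        od = rng.uniform(0, 1, (80, 80))
        vessel = np.zeros_like(od, dtype=bool)
        vessel[10:20, 10:20] = True
        area, med = stromal_metrics(od, vessel, 4.0, stroma_threshold_od=0.15)
        vals = np.sort(od[(od >= 0.15) & ~vessel])
        assert med == pytest.approx(float(np.median(vals)))
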