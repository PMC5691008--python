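"""Voxel phantoms, HU mapping and exact ray traversal."""

import numpy as np
import pytest

from ctkvdose.geometry import (HUMapping, VoxelPhantom, apply_hu_mapping,
                               build_cylinder_phantom, radiological_path,
                               ray_trace)
from ctkvdose.materials import get_material


@pytest.fixture(scope="module")
def small_cylinder():
    return build_cylinder_phantom(15.2, 4.0, get_material("pmma"),
                                  spacing_cm=0.4)


def water_box(n=10, spacing=0.5, density=1.0):
    water = get_material("water")
    half = n * spacing / 2
    return VoxelPhantom(
        origin_cm=np.array([-half] * 3),
        spacing_cm=np.array([spacing] * 3),
        material_index=np.zeros((n, n, n), dtype=np.int16),
        density=np.full((n, n, n), density),
        materials=[water],
    )


class TestCylinderPhantom:
    def test_center_voxel_is_the_cylinder_material(self, small_cylinder):
        assert small_cylinder.material_at((0, 0, 0)).name == "pmma"

    def test_corner_voxel_is_air(self, small_cylinder):
        u = small_cylinder.upper_cm - 0.01
        assert small_cylinder.material_at(u).name == "air"

    def test_cross_section_area_converges(self):
        ph = build_cylinder_phantom(15.2, 0.4, get_material("pmma"),
                                    spacing_cm=0.1)
        n_pmma = np.sum(ph.material_index[:, :, 0] == 1)
        area = n_pmma * 0.1**2
        assert area == pytest.approx(np.pi * 7.6**2, rel=0.01)

    def test_spacing_larger_than_diameter_rejected(self):
        with pytest.raises(ValueError):
            build_cylinder_phantom(1.0, 5.0, get_material("pmma"),
                                   spacing_cm=2.0)


class TestHUMapping:
    @pytest.fixture
    def mapping(self):
        return HUMapping(rows=[
            (-1100.0, -900.0, get_material("air"), 0.0012),
            (-900.0, 100.0, get_material("soft_tissue"), 1.06),
            (100.0, 2000.0, get_material("cortical_bone"), 1.92),
        ])

    def test_single_range_gives_uniform_phantom(self):
        mapping = HUMapping(rows=[(-2000.0, 2000.0,
                                   get_material("water"), 1.0)])
        hu = np.random.default_rng(0).uniform(-500, 500, (4, 4, 4))
        ph = apply_hu_mapping(hu, mapping, [0, 0, 0], [1, 1, 1])
        assert np.all(ph.material_index == 0)
        assert np.all(ph.density == 1.0)

    def test_boundary_value_goes_to_upper_range(self, mapping):
        hu = np.full((2, 2, 2), 100.0)  # exactly on a breakpoint
        ph = apply_hu_mapping(hu, mapping, [0, 0, 0], [1, 1, 1])
        assert ph.materials[ph.material_index[0, 0, 0]].name \
            == "cortical_bone"

    def test_uncovered_value_cited_in_error(self, mapping):
        hu = np.full((2, 2, 2), -1500.0)
        with pytest.raises(ValueError, match="-1500"):
            apply_hu_mapping(hu, mapping, [0, 0, 0], [1, 1, 1])

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError):
            HUMapping(rows=[(-100.0, 100.0, get_material("water"), 1.0),
                            (50.0, 200.0, get_material("water"), 1.0)])


class TestRayTrace:
    def test_axis_aligned_ray_equal_chords(self):
        ph = water_box(n=10, spacing=0.5)
        out = ray_trace(ph, (-10, 0.1, 0.1), (10, 0.1, 0.1))
        assert len(out) == 10
        for (_, chord) in out:
            assert chord == pytest.approx(0.5, rel=1e-9)
        assert [v[0][0] for v in out] == list(range(10))

    def test_ray_missing_grid_is_empty(self):
        ph = water_box()
        assert ray_trace(ph, (100, 100, 0), (101, 100, 0)) == []

    def test_chord_sum_equals_clipped_length(self):
        ph = water_box(n=12, spacing=0.37)
        rng = np.random.default_rng(5)
        for _ in range(1000):
            p0 = rng.uniform(-6, 6, 3)
            p1 = rng.uniform(-6, 6, 3)
            if np.allclose(p0, p1):
                continue
            chords = sum(c for _, c in ray_trace(ph, p0, p1))
            # clip segment to the box analytically
            d = p1 - p0
            length = np.linalg.norm(d)
            d = d / length
            lo, hi = ph.origin_cm, ph.upper_cm
            with np.errstate(divide="ignore"):
                ta = (lo - p0) / d
                tb = (hi - p0) / d
            t0 = np.nanmax(np.minimum(ta, tb))
            t1 = np.nanmin(np.maximum(ta, tb))
            expected = max(0.0, min(t1, length) - max(t0, 0.0))
            assert chords == pytest.approx(expected, abs=1e-9 * max(1, length))

    def test_traversal_is_reversible(self):
        ph = water_box(n=8, spacing=0.6)
        p0, p1 = (-5, -1.3, 0.7), (5, 2.1, -1.9)
        # ignore degenerate sliver chords from boundary rounding
        fwd = [(v, c) for v, c in ray_trace(ph, p0, p1) if c > 1e-9]
        bwd = [(v, c) for v, c in ray_trace(ph, p1, p0) if c > 1e-9]
        assert [v for v, _ in fwd] == [v for v, _ in bwd][::-1]
        np.testing.assert_allclose([c for _, c in fwd],
                                   [c for _, c in bwd][::-1], atol=1e-9)

    def test_degenerate_segment_rejected(self):
        ph = water_box()
        with pytest.raises(ValueError):
            ray_trace(ph, (0, 0, 0), (0, 0, 0))


class TestRadiologicalPath:
    def test_vacuum_is_zero(self):
        ph = water_box(density=0.0)
        assert radiological_path(ph, (-10, 0, 0), (10, 0, 0), 60.0) == 0.0

    def test_homogeneous_matches_uniform_limit(self):
        ph = water_box(n=10, spacing=0.5)
        tau = radiological_path(ph, (-10, 0.1, 0.1), (10, 0.1, 0.1), 60.0)
        mu = get_material("water").linear_attenuation(60.0)
        assert tau == pytest.approx(mu * 5.0, rel=1e-9)

    def test_two_slab_hand_sum(self):
        water = get_material("water")
        pmma = get_material("pmma")
        mat = np.zeros((10, 4, 4), dtype=np.int16)
        mat[5:, :, :] = 1
        dens = np.where(mat == 0, 1.0, 1.18)
        ph = VoxelPhantom(origin_cm=np.array([0.0, 0.0, 0.0]),
                          spacing_cm=np.array([0.5, 0.5, 0.5]),
                          material_index=mat, density=dens,
                          materials=[water, pmma])
        tau = radiological_path(ph, (-1, 1.1, 1.1), (6, 1.1, 1.1), 50.0)
        expected = water.linear_attenuation(50.0) * 2.5 \
            + pmma.linear_attenuation(50.0) * 2.5
        assert tau == pytest.approx(expected, rel=1e-9)

    def test_additive_over_concatenation(self):
        ph = water_box(n=12, spacing=0.37)
        a, b, c = (-5, 0.3, -0.2), (0.11, 0.5, 0.33), (5, -1.2, 1.0)
        tau_ab = radiological_path(ph, a, b, 80.0)
        tau_bc = radiological_path(ph, b, c, 80.0)
        # additivity holds for collinear splits; use a straight segment
        m = tuple((np.array(a) + np.array(c)) / 2)
        tau_full = radiological_path(ph, a, c, 80.0)
        tau_split = radiological_path(ph, a, m, 80.0) \
            + radiological_path(ph, m, c, 80.0)
        assert tau_full == pytest.approx(tau_split, abs=1e-9)
        assert tau_ab >= 0 and tau_bc >= 0


class TestPhantomIO:
    def test_nrrd_round_trip(self, tmp_path, small_cylinder):
        base = tmp_path / "cyl"
        small_cylinder.save(base)
        loaded = VoxelPhantom.load(base)
        np.testing.assert_array_equal(loaded.material_index,
                                      small_cylinder.material_index)
        np.testing.assert_allclose(loaded.density, small_cylinder.density,
                                   rtol=1e-6)
        np.testing.assert_allclose(loaded.origin_cm,
                                   small_cylinder.origin_cm)
        assert [m.name for m in loaded.materials] \
            == [m.name for m in small_cylinder.materials]
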