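"""Scene module: materials, grids, plate/source rasterization."""

import math

import numpy as np
import pytest
from scipy import integrate

import tfusim as tf
from tfusim.exceptions import (ConfigSchemaError, GeometryError,
                               InvalidConfigError)
from tfusim.scene import (ACRYLIC, WATER, Material, PlateSpec, SceneConfig,
                          TransducerSpec, build_grid, build_medium_maps,
                          build_source, mask_volume, rasterize_plate,
                          reference_scene)


class TestMaterial:
    def test_table_values_and_derived_quantities(self):
        # water: alpha = 0.02 * 0.9 Np/m, delta = 2 alpha c^3 / omega^2
        f = 0.9e6
        omega = 2 * math.pi * f
        assert WATER.alpha_np(f) == pytest.approx(0.018)
        assert WATER.diffusivity(f) == pytest.approx(
            2 * 0.018 * 1482.0**3 / omega**2, rel=1e-12)
        assert WATER.diffusivity(f) == pytest.approx(3.66e-6, rel=0.01)
        assert ACRYLIC.alpha_np(f) == pytest.approx(16.2)
        assert WATER.impedance == pytest.approx(998.2 * 1482.0)

    def test_zero_absorption_gives_zero_diffusivity(self):
        m = Material(1000.0, 1500.0, 0.0, 1.0)
        assert m.diffusivity(0.9e6) == 0.0

    def test_db_per_m_constructor_matches_neper_conversion(self):
        m = Material.from_db_per_m(1850.0, 3500.0, 2600.0, 0.9e6)
        assert m.alpha_np(0.9e6) == pytest.approx(2600.0 / 8.685889638,
                                                  rel=1e-9)

    @pytest.mark.parametrize("kw", [dict(density=-1.0, sound_speed=1500.0),
                                    dict(density=1000.0, sound_speed=0.0),
                                    dict(density=1000.0, sound_speed=1500.0,
                                         absorption=-2.0)])
    def test_invalid_materials_rejected(self, kw):
        with pytest.raises(InvalidConfigError):
            Material(**kw)


class TestGrid:
    def test_study_grid_is_500_cubed_and_10ns_is_stable(self):
        grid = build_grid("3d", 0.2e-3, 10e-9, (0.1, 0.1, 0.1), c_max=5000.0)
        assert grid.shape == (500, 500, 500)
        # classical bound dx/(c sqrt(3)) = 23.09 ns
        from tfusim.scene import cfl_dt_max
        assert cfl_dt_max(0.2e-3, 5000.0, "3d") == pytest.approx(23.09e-9,
                                                                 rel=1e-3)

    def test_axisymmetric_half_plane_coordinates(self):
        grid = build_grid("axisymmetric", 0.4e-3, 20e-9, (0.1, 0.05))
        assert grid.r[0] == pytest.approx(0.2e-3)
        assert grid.r[-1] < 0.05 and grid.z[-1] < 0.1
        assert grid.shape == (250, 125)

    def test_unstable_dt_rejected(self):
        with pytest.raises(InvalidConfigError):
            build_grid("3d", 0.2e-3, 30e-9, (0.1, 0.1, 0.1), c_max=5000.0)

    def test_bad_extent_count_rejected(self):
        with pytest.raises(InvalidConfigError):
            build_grid("axisymmetric", 0.4e-3, 20e-9, (0.1,))


@pytest.fixture
def coarse_grid():
    return build_grid("axisymmetric", 0.4e-3, 20e-9, (0.1, 0.05))


@pytest.fixture
def transducer():
    return tf.default_transducer()


class TestPlateRasterization:
    def test_on_axis_chord_equals_thickness(self, coarse_grid, transducer):
        plate = PlateSpec(8e-3, 60e-3, 10e-3, ACRYLIC)
        mask = rasterize_plate(plate, coarse_grid, transducer)
        chord = mask[:, 0].sum() * coarse_grid.dx
        assert chord == pytest.approx(8e-3, abs=coarse_grid.dx)

    def test_flat_slab_limit_volume(self, coarse_grid, transducer):
        # R -> very large: the shell converges to a flat slab of thickness T
        plate = PlateSpec(8e-3, 5.0, 10e-3, ACRYLIC)
        mask = rasterize_plate(plate, coarse_grid, transducer)
        vol = mask_volume(mask, coarse_grid)
        slab = math.pi * 0.05**2 * 8e-3
        assert vol == pytest.approx(slab, rel=0.02)

    def test_shell_volume_matches_quadrature(self, transducer):
        # independent oracle: area integral of the clipped annulus per z
        grid = build_grid("axisymmetric", 0.2e-3, 20e-9, (0.1, 0.05))
        plate = PlateSpec(8e-3, 60e-3, 10e-3, ACRYLIC)
        mask = rasterize_plate(plate, grid, transducer)
        z0 = transducer.rim_z + 10e-3
        zc = z0 + 60e-3
        r_ext = grid.extents[1]

        def area(z):
            def sq(radius):
                h2 = radius**2 - (z - zc) ** 2
                return min(max(h2, 0.0), r_ext**2)
            return math.pi * (sq(60e-3) - sq(52e-3))

        vol, _ = integrate.quad(area, z0, grid.extents[0], limit=400)
        assert mask_volume(mask, grid) == pytest.approx(vol, rel=0.02)

    def test_resolution_consistency(self, transducer):
        plate = PlateSpec(8e-3, 60e-3, 10e-3, ACRYLIC)
        vols = []
        for dx in (0.4e-3, 0.2e-3):
            grid = build_grid("axisymmetric", dx, 20e-9, (0.1, 0.05))
            vols.append(mask_volume(rasterize_plate(plate, grid, transducer),
                                    grid))
        assert abs(vols[1] - vols[0]) / vols[1] < 0.01

    def test_plate_touching_source_rejected(self, coarse_grid, transducer):
        # flat plate flush against the rim plane cuts the cap rim
        plate = PlateSpec(8e-3, 1.0e3, 0.0, ACRYLIC)
        with pytest.raises(GeometryError):
            rasterize_plate(plate, coarse_grid, transducer)

    def test_axisymmetric_and_3d_axial_profiles_agree(self, transducer):
        plate = PlateSpec(8e-3, 60e-3, 10e-3, ACRYLIC)
        g2 = build_grid("axisymmetric", 1e-3, 20e-9, (0.1, 0.05))
        g3 = build_grid("3d", 1e-3, 20e-9, (0.1, 0.1, 0.1))
        m2 = rasterize_plate(plate, g2, transducer)
        m3 = rasterize_plate(plate, g3, transducer)
        ny, nx = g3.shape[1:]
        np.testing.assert_array_equal(m2[:, 0], m3[:, ny // 2, nx // 2])


class TestMediumMaps:
    def test_partition_and_values(self, transducer):
        plate = PlateSpec(8e-3, 60e-3, 10e-3, ACRYLIC)
        scene = reference_scene(plate=plate, resolution="coarse")
        maps = build_medium_maps(scene)
        f = transducer.frequency
        water_cells = ~maps.plate_mask
        assert np.all(maps.c[water_cells] == WATER.sound_speed)
        assert np.all(maps.c[maps.plate_mask] == ACRYLIC.sound_speed)
        assert np.all(maps.rho[maps.plate_mask] == ACRYLIC.density)
        assert maps.delta[maps.plate_mask].max() == pytest.approx(
            ACRYLIC.diffusivity(f), rel=1e-12)
        # every cell carries exactly one material
        assert set(np.unique(maps.rho)) == {WATER.density, ACRYLIC.density}

    def test_lossless_scene_has_zero_delta(self):
        m = Material(998.2, 1482.0, 0.0, 0.0)
        scene = reference_scene(resolution="coarse").with_(background=m)
        maps = build_medium_maps(scene)
        assert np.all(maps.delta == 0.0)


class TestSource:
    def test_annular_cap_projected_radii(self, coarse_grid, transducer):
        src = build_source(transducer, coarse_grid)
        radii = coarse_grid.r[src.indices[1]]
        assert radii.min() >= 25e-3 - coarse_grid.dx
        assert radii.max() <= 50e-3
        # rim depth of the 100 mm bowl: 80 - sqrt(80^2 - 50^2) mm
        assert transducer.rim_z == pytest.approx(17.55e-3, abs=1e-5)

    def test_cap_subtends_half_angle(self):
        theta = math.radians(30.0)
        tr = TransducerSpec(frequency=0.9e6,
                           aperture_diameter=2 * 0.08 * math.sin(theta),
                           focal_length=0.08, hole_diameter=0.0)
        assert tr.half_angle == pytest.approx(theta, rel=1e-12)

    def test_drive_amplitude_proportional_to_p0(self, coarse_grid, transducer):
        from dataclasses import replace
        s1 = build_source(transducer, coarse_grid)
        s2 = build_source(replace(transducer, surface_pressure=2e4),
                          coarse_grid)
        np.testing.assert_array_equal(s2.value(1e-6), 2.0 * s1.value(1e-6))

    def test_cap_exceeding_domain_rejected(self, transducer):
        grid = build_grid("axisymmetric", 0.4e-3, 20e-9, (0.1, 0.03))
        with pytest.raises(GeometryError):
            build_source(transducer, grid)


class TestSceneConfig:
    def test_yaml_round_trip(self, tmp_path):
        plate = PlateSpec(8e-3, 60e-3, 10e-3, ACRYLIC)
        scene = reference_scene(plate=plate, resolution="coarse")
        path = tmp_path / "scene.yaml"
        scene.to_yaml(path)
        loaded = SceneConfig.from_yaml(path)
        assert loaded == scene
        assert loaded.hash() == scene.hash()

    def test_missing_key_names_the_key(self):
        with pytest.raises(ConfigSchemaError, match="grid"):
            SceneConfig.from_dict({"transducer": {}})

    def test_points_per_wavelength(self):
        scene = reference_scene(resolution="coarse")
        assert scene.points_per_wavelength == pytest.approx(4.0)
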