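"""Solver physics: stability, dispersion, absorption, boundaries, sources,
linearity, nonlinearity, and cross-mode agreement."""

import math
import warnings
from dataclasses import replace

import numpy as np
import pytest

import tfusim as tf
from tfusim.exceptions import DivergenceError, InvalidConfigError
from tfusim.fixtures import (ACRYLIC_LOSSLESS, WATER_LOSSLESS, make_fixture,
                             mini_bowl_scene)
from tfusim.oracles import (fubini_harmonics, interface_transmission,
                            oneil_onaxis, plane_wave_decay, shock_parameter)
from tfusim.scene import (ACRYLIC, WATER, Material, PlateSpec, SceneConfig,
                          TransducerSpec, build_grid, build_medium_maps,
                          build_source, choose_time_step)
from tfusim.solver import (SolverSettings, SolverState, check_stability,
                           run_to_steady, step)

F0 = 0.9e6
OMEGA = 2 * math.pi * F0


def scene_1d(medium, length=0.06, ppw=16, steps_per_period=40, p0=1e4,
             plate=None, aperture=0.02):
    tr = TransducerSpec(frequency=F0, aperture_diameter=aperture,
                        focal_length=1.0, hole_diameter=0.0,
                        surface_pressure=p0)
    dx = medium.sound_speed / F0 / ppw
    c_max = medium.sound_speed if plate is None else max(
        medium.sound_speed, plate.material.sound_speed)
    d_max = medium.effective_diffusivity(F0) if plate is None else max(
        medium.effective_diffusivity(F0),
        plate.material.effective_diffusivity(F0))
    dt = min(choose_time_step(dx, "1d", c_max, d_max),
             1.0 / (steps_per_period * F0))
    grid = build_grid("1d", dx, dt, (length,), c_max=c_max)
    return SceneConfig(grid=grid, transducer=tr, background=medium,
                       plate=plate)


def lstsq_amp(t, sig, omega=OMEGA):
    a = np.column_stack([np.sin(omega * t), np.cos(omega * t)])
    coef, *_ = np.linalg.lstsq(a, sig, rcond=None)
    return math.hypot(*coef)


class TestStability:
    def test_classical_cfl_values(self):
        # the bound depends only on dx and c_max, so a small 3d grid suffices
        grid = build_grid("3d", 0.2e-3, 10e-9, (0.01, 0.01, 0.01),
                          c_max=5000.0)
        tr = TransducerSpec(frequency=0.9e6, aperture_diameter=8e-3,
                            focal_length=8e-3, hole_diameter=0.0)
        scene = SceneConfig(grid=grid, transducer=tr,
                            background=Material(1000.0, 5000.0, 0.0, 0.0))
        rep = check_stability(grid, build_medium_maps(scene))
        assert rep.dt_max_cfl == pytest.approx(23.09e-9, rel=1e-3)
        assert rep.passes
        slow = scene.with_(background=Material(1000.0, 1482.0, 0.0, 0.0))
        rep2 = check_stability(grid, build_medium_maps(slow))
        assert rep2.dt_max_cfl == pytest.approx(77.9e-9, rel=1e-3)

    def test_cfl_inversely_proportional_to_speed(self):
        from tfusim.scene import cfl_dt_max
        assert cfl_dt_max(0.2e-3, 5000.0, "3d") == pytest.approx(
            cfl_dt_max(0.2e-3, 2500.0, "3d") / 2.0, rel=1e-12)

    def test_run_rejects_unstable_dt(self):
        med = Material(998.2, 1482.0, 0.0, 0.0)
        dx = med.sound_speed / F0 / 8
        grid = build_grid("1d", dx, 0.95 * dx / med.sound_speed, (0.02,),
                          c_max=med.sound_speed)
        scene = scene_1d(med).with_(grid=grid)
        # above the 8th-order scheme bound (0.784 dx/c) but below classical
        with pytest.raises(InvalidConfigError):
            run_to_steady(scene)

    def test_blowup_detection(self):
        scene = scene_1d(WATER, length=0.02)
        with pytest.raises(DivergenceError):
            run_to_steady(scene, SolverSettings(blowup_factor=1e-9,
                                                check_every=50))


class TestStep:
    def test_zero_field_stays_zero(self):
        scene = scene_1d(WATER, length=0.01)
        grid = scene.grid
        media = build_medium_maps(scene)
        state = SolverState.zeros(grid)
        for _ in range(20):
            step(state, media, None, grid)
        assert np.all(state.p0 == 0.0)

    def test_static_boundary_stays_zero(self):
        # Mur update maps zeros to zeros
        scene = mini_bowl_scene(WATER_LOSSLESS, ppw=6)
        media = build_medium_maps(scene.with_(plate=None))
        state = SolverState.zeros(scene.grid)
        step(state, media, None, scene.grid)
        assert np.all(state.p0 == 0.0)


class TestPlaneWavePhysics:
    def test_phase_speed_within_half_percent_at_8ppw(self):
        med = WATER_LOSSLESS
        scene = scene_1d(med, length=0.05, ppw=8)
        lam = med.sound_speed / F0
        z1, z2 = 10 * lam, 20 * lam
        fld = run_to_steady(scene, SolverSettings(linear=True, lossless=True),
                            probes=[(z1,), (z2,)])
        dt = fld.probes["dt_s"]
        series = fld.probes["series"]
        n = series.shape[0]
        t = (np.arange(n) + 1) * dt
        tail = t > t[-1] - 8 / F0
        phases = []
        for m in range(2):
            a = np.column_stack([np.sin(OMEGA * t[tail]),
                                 np.cos(OMEGA * t[tail])])
            coef, *_ = np.linalg.lstsq(a, series[tail, m], rcond=None)
            phases.append(math.atan2(coef[1], coef[0]))
        # probes are an integer number of wavelengths apart up to grid snap
        grid = scene.grid
        dz = (grid.z[np.argmin(abs(grid.z - z2))]
              - grid.z[np.argmin(abs(grid.z - z1))])
        k0 = OMEGA / med.sound_speed
        dphi = phases[0] - phases[1]
        cycles = (k0 * dz - dphi) / (2 * math.pi)
        k_num = (dphi + 2 * math.pi * round(cycles)) / dz
        c_num = OMEGA / k_num
        assert abs(c_num / med.sound_speed - 1) < 0.005

    def test_amplitude_decay_matches_exponential(self):
        # alpha = 50 Np/m over ~20 wavelengths
        med = Material(998.2, 1482.0, 50.0 / 0.9, 0.0)
        scene = scene_1d(med, length=0.06)
        fld = run_to_steady(scene, SolverSettings(
            linear=True, amplitude_method="quadrature"))
        z, amp = fld.on_axis()
        sel = (z > 0.005) & (z < 0.035)
        slope = np.polyfit(z[sel], np.log(amp[sel]), 1)[0]
        assert -slope == pytest.approx(50.0, rel=0.02)

    def test_mur_normal_incidence_reflection_below_1pct(self):
        scene = scene_1d(WATER_LOSSLESS, length=0.06)
        fld = run_to_steady(scene, SolverSettings(
            linear=True, lossless=True, amplitude_method="quadrature"))
        z, amp = fld.on_axis()
        lam = WATER_LOSSLESS.sound_speed / F0
        sel = (z > 0.06 - 3 * lam) & (z < 0.06 - lam / 4)
        swr = (amp[sel].max() - amp[sel].min()) / (amp[sel].max()
                                                   + amp[sel].min())
        assert swr < 0.01

    def test_interface_transmission_matches_impedance_formula(self):
        # lossless water -> acrylic half-space, transient windowing
        plate = PlateSpec(thickness=55e-3, curvature_radius=10.0,
                          standoff=60e-3, material=ACRYLIC_LOSSLESS)
        scene = scene_1d(WATER_LOSSLESS, length=0.12, plate=plate)
        c1 = WATER_LOSSLESS.sound_speed
        zi, p1z, p2z = 0.060, 0.040, 0.070
        fld = run_to_steady(scene, SolverSettings(linear=True, lossless=True),
                            probes=[(p1z,), (p2z,)], duration=100e-6)
        dt = fld.probes["dt_s"]
        series = fld.probes["series"]
        t = (np.arange(series.shape[0]) + 1) * dt
        w1 = (t > p1z / c1 + 5 / F0) & (t < (2 * zi - p1z) / c1)
        a1 = lstsq_amp(t[w1], series[w1, 0])
        t2a = zi / c1 + (p2z - zi) / ACRYLIC_LOSSLESS.sound_speed
        w2 = (t > t2a + 5 / F0) & (t < t2a + 25 / F0)
        a2 = lstsq_amp(t[w2], series[w2, 1])
        expect = interface_transmission(WATER_LOSSLESS, ACRYLIC_LOSSLESS)
        assert a2 / a1 == pytest.approx(expect, rel=0.02)

    def test_slab_transmission_matches_closed_form(self):
        # acrylic slab: interface product x Beer-Lambert decay within 3%
        scene = make_fixture("slab_1d")
        plate = scene.plate
        c1, c2 = WATER.sound_speed, ACRYLIC.sound_speed
        zi, L = plate.standoff, plate.thickness
        p1z, p2z = 0.040, 0.075
        fld = run_to_steady(scene, SolverSettings(linear=True),
                            probes=[(p1z,), (p2z,)], duration=110e-6)
        dt = fld.probes["dt_s"]
        series = fld.probes["series"]
        t = (np.arange(series.shape[0]) + 1) * dt
        w1 = (t > p1z / c1 + 5 / F0) & (t < (2 * zi - p1z) / c1)
        a1 = lstsq_amp(t[w1], series[w1, 0])
        t2a = zi / c1 + L / c2 + (p2z - zi - L) / c1
        w2 = (t > t2a + 8 / F0) & (t < t2a + 30 / F0)
        a2 = lstsq_amp(t[w2], series[w2, 1])
        expect = (interface_transmission(WATER, ACRYLIC)
                  * interface_transmission(ACRYLIC, WATER)
                  * plane_wave_decay(ACRYLIC.alpha_np(F0), L))
        assert a2 / a1 == pytest.approx(expect, rel=0.03)

    def test_second_harmonic_matches_fubini(self):
        med = Material(998.2, 1482.0, 0.0, 3.5)
        p0 = 1.5e6
        scene = scene_1d(med, length=0.04, ppw=24, steps_per_period=40,
                         p0=p0)
        src_z = scene.grid.z[4]  # transparent sheet source offset
        probe_z = 0.033
        fld = run_to_steady(scene, SolverSettings(linear=False,
                                                  lossless=True),
                            probes=[(probe_z,)])
        dt = fld.probes["dt_s"]
        series = fld.probes["series"][:, 0]
        t = (np.arange(len(series)) + 1) * dt
        tail = t > t[-1] - 10 / F0
        a = np.column_stack([np.sin(OMEGA * t[tail]),
                             np.cos(OMEGA * t[tail]),
                             np.sin(2 * OMEGA * t[tail]),
                             np.cos(2 * OMEGA * t[tail]),
                             np.ones(tail.sum())])
        coef, *_ = np.linalg.lstsq(a, series[tail], rcond=None)
        a1 = math.hypot(coef[0], coef[1])
        a2 = math.hypot(coef[2], coef[3])
        sigma = shock_parameter(p0, med, F0, probe_z - src_z)
        expect = fubini_harmonics(sigma, 2) / fubini_harmonics(sigma, 1)
        assert a2 / a1 == pytest.approx(expect, rel=0.10)


class TestFocusedBowl:
    def test_focal_gain_matches_oneil_within_5pct(self, mini_bowl_field):
        fld, scene = mini_bowl_field
        z, prof = fld.on_axis()
        orc = oneil_onaxis(scene.transducer, WATER_LOSSLESS, z)
        assert prof.max() == pytest.approx(orc.max(), rel=0.05)
        z_sim = z[np.argmax(prof)]
        z_orc = z[np.argmax(orc)]
        assert abs(z_sim - z_orc) <= 2 * scene.grid.dx

    def test_exact_linearity_in_p0(self):
        scene = mini_bowl_scene(WATER_LOSSLESS, ppw=6)
        s = SolverSettings(linear=True, lossless=True)
        f1 = run_to_steady(scene, s)
        tr2 = replace(scene.transducer, surface_pressure=2e4)
        f2 = run_to_steady(scene.with_(transducer=tr2), s)
        np.testing.assert_array_equal(f2.data, 2.0 * f1.data)

    def test_monotone_dissipation(self):
        # increasing delta never increases the focal amplitude
        peaks = []
        for alpha0 in (0.0, 5.0, 20.0):
            med = Material(998.2, 1482.0, alpha0, 0.0)
            scene = mini_bowl_scene(med, ppw=6)
            fld = run_to_steady(scene, SolverSettings(linear=True))
            peaks.append(fld.data.max())
        assert peaks[0] >= peaks[1] >= peaks[2]
        assert peaks[2] < 0.9 * peaks[0]

    def test_grid_convergence(self):
        peaks = {}
        for ppw in (6, 12):
            scene = mini_bowl_scene(WATER_LOSSLESS, ppw=ppw)
            fld = run_to_steady(scene, SolverSettings(
                linear=True, lossless=True, amplitude_method="quadrature"))
            peaks[ppw] = fld.data.max()
        assert peaks[6] == pytest.approx(peaks[12], rel=0.03)

    def test_axisymmetric_and_3d_agree(self):
        sax = mini_bowl_scene(WATER_LOSSLESS, ppw=6, mode="axisymmetric")
        s3d = mini_bowl_scene(WATER_LOSSLESS, ppw=6, mode="3d")
        settings = SolverSettings(linear=True, lossless=True,
                                  amplitude_method="quadrature")
        fax = run_to_steady(sax, settings)
        f3d = run_to_steady(s3d, settings)
        za, pa = fax.on_axis()
        z3, p3 = f3d.on_axis()
        assert p3.max() == pytest.approx(pa.max(), rel=0.02)
        assert (abs(za[np.argmax(pa)] - z3[np.argmax(p3)])
                <= sax.grid.dx + 1e-9)

    def test_steady_state_residual_is_reported_and_small(self, water_field):
        assert water_field.meta["residual"] < 0.01

    def test_short_run_warns_about_nonconvergence(self):
        scene = mini_bowl_scene(WATER_LOSSLESS, ppw=6)
        with pytest.warns(RuntimeWarning, match="steady-state"):
            run_to_steady(scene, SolverSettings(linear=True),
                          duration=20e-6)
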