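"""Heat-transport model: kernels, superposition, isotherms, sweeps."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from focalheat.heat_model import (
    IsothermReport,
    LaserProtocol,
    Medium,
    SourceModel,
    TemperatureField,
    crossing_radius,
    cw_steady_state,
    heat_kernel,
    isotherm_extent,
    lateral_isotherm_radius,
    lateral_profile,
    normalize_to_peak,
    parameter_sweep,
    peak_delta_t,
    pulse_train_field,
)

from _oracles import radial_steady_profile


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class TestDomainTypes:
    def test_medium_diffusivity_derived_and_checked(self):
        m = Medium(thermal_conductivity=0.6, volumetric_heat_capacity=4.18e6)
        assert m.thermal_diffusivity == pytest.approx(0.6 / 4.18e6, rel=1e-12)
        with pytest.raises(ValueError, match="inconsistent"):
            Medium(thermal_diffusivity=2e-7)
        with pytest.raises(ValueError):
            Medium(thermal_conductivity=-1.0)

    def test_protocol_duty_cycle_bounds(self):
        with pytest.raises(ValueError, match="duty cycle"):
            LaserProtocol(mode="pulsed", repetition_frequency_hz=1000.0,
                          pulse_length_ms=1.5)
        p = LaserProtocol(mode="pulsed", repetition_frequency_hz=1000.0,
                          pulse_length_ms=1.0)
        assert p.duty_cycle == pytest.approx(1.0)
        assert LaserProtocol(mode="cw", repetition_frequency_hz=None,
                             pulse_length_ms=None).duty_cycle == 1.0

    def test_source_requires_axial_elongation(self):
        with pytest.raises(ValueError, match="elongated"):
            SourceModel(lateral_radius_um=2.0, axial_radius_um=1.0)

    def test_field_rejects_negative_and_nonfinite(self):
        x = np.arange(3.0)
        good = np.zeros((3, 3, 3))
        TemperatureField(x, x, x, good, 23.0, "steady_state")
        with pytest.raises(ValueError, match="negative"):
            TemperatureField(x, x, x, good - 1.0, 23.0, "steady_state")
        bad = good.copy()
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            TemperatureField(x, x, x, bad, 23.0, "steady_state")

    def test_isotherm_report_volume_is_ellipsoid(self):
        rep = IsothermReport(35.0, 3.0, 6.0)
        assert rep.heated_volume_um3 == pytest.approx(4 / 3 * math.pi * 9 * 6)
        with pytest.raises(ValueError):
            IsothermReport(35.0, -1.0, 2.0)


# ---------------------------------------------------------------------------
# heat kernel
# ---------------------------------------------------------------------------


class TestHeatKernel:
    def test_zero_energy_and_far_field_vanish(self, water):
        assert heat_kernel(5e-6, 1e-4, 0.0, water) == 0.0
        # off the origin the exponential dominates as t -> 0+
        assert heat_kernel(10e-6, 1e-12, 1e-6, water) == pytest.approx(0.0, abs=1e-300)

    def test_rejects_nonpositive_time(self, water):
        with pytest.raises(ValueError, match="t > 0"):
            heat_kernel(1e-6, 0.0, 1e-6, water)

    def test_gaussian_shape_in_r(self, water):
        t, E = 1e-4, 1e-6
        r = np.array([0.0, 2e-6, 4e-6])
        v = heat_kernel(r, t, E, water)
        width2 = 4 * water.thermal_diffusivity * t
        # log of a Gaussian is quadratic in r
        assert np.log(v[1] / v[0]) == pytest.approx(-(2e-6) ** 2 / width2, rel=1e-9)
        assert np.log(v[2] / v[0]) == pytest.approx(-(4e-6) ** 2 / width2, rel=1e-9)

    @pytest.mark.parametrize("t_s", [1e-5, 1e-4, 1e-3])
    def test_energy_conserved_by_quadrature(self, water, t_s):
        """Volume integral of rho*c*dT recovers the deposited energy <0.1%."""
        E = 2.5e-6
        rho_c = water.volumetric_heat_capacity
        width = math.sqrt(4 * water.thermal_diffusivity * t_s)
        integral, _ = quad(
            lambda r: rho_c * heat_kernel(r, t_s, E, water) * 4 * math.pi * r**2,
            0.0, 30 * width, limit=200,
        )
        assert integral == pytest.approx(E, rel=1e-3)


# ---------------------------------------------------------------------------
# CW steady state
# ---------------------------------------------------------------------------


class TestCwSteadyState:
    def test_zero_power_and_inverse_distance(self, water, isotropic_source):
        r = np.array([4e-6, 8e-6, 16e-6])
        assert np.all(cw_steady_state(r, 0.0, water, isotropic_source) == 0.0)
        v = cw_steady_state(r, 1e-3, water, isotropic_source)
        # halving with distance doubling, outside the source
        assert v[0] / v[1] == pytest.approx(2.0, rel=2e-3)
        assert v[1] / v[2] == pytest.approx(2.0, rel=2e-3)
        assert np.all(np.diff(v) < 0)

    def test_point_source_singularity_handling(self, water):
        with pytest.raises(ValueError, match="singular"):
            cw_steady_state(0.0, 1e-3, water)
        src = SourceModel(geometry="point", lateral_radius_um=1.0, axial_radius_um=1.0)
        capped = cw_steady_state(0.0, 1e-3, water, src)
        assert capped == pytest.approx(cw_steady_state(1e-6, 1e-3, water, src))

    def test_matches_radial_conduction_oracle(self, water, isotropic_source):
        """Independent quadrature of the steady conduction ODE, RMS < 2%."""
        w0 = isotropic_source.lateral_radius_um * 1e-6
        r = np.linspace(2 * w0, 20e-6, 50)
        r_far = 2e-4
        oracle = radial_steady_profile(r, 1e-3, water, w0, r_max_m=r_far)
        mine = cw_steady_state(r, 1e-3, water, isotropic_source) - cw_steady_state(
            r_far, 1e-3, water, isotropic_source
        )
        rms = np.sqrt(np.mean((mine - oracle) ** 2) / np.mean(oracle**2))
        assert rms < 0.02


# ---------------------------------------------------------------------------
# pulse trains
# ---------------------------------------------------------------------------


def _xz_grid(extent_um=10.0, n=41):
    axis = np.linspace(-extent_um, extent_um, n)
    return axis, np.zeros(1), axis


class TestPulseTrain:
    def test_duty_cycle_one_equals_cw(self, water, isotropic_source):
        proto = LaserProtocol(mode="pulsed", repetition_frequency_hz=1000.0,
                              pulse_length_ms=1.0)
        grid = _xz_grid()
        f = pulse_train_field(proto, water, isotropic_source, grid, "in_pulse_peak")
        x, _, z = grid
        r = np.sqrt((x[None, None, :] * 1e-6) ** 2 + (z[:, None, None] * 1e-6) ** 2)
        cw = cw_steady_state(r, proto.absorbed_power_w, water, isotropic_source)
        assert np.max(np.abs(f.values - cw)) < 0.01 * cw.max()

    def test_single_pulse_matches_direct_kernel_integration(self, water):
        """One pulse at its end == time integral of the point-release kernel."""
        src = SourceModel(geometry="point", lateral_radius_um=0.5,
                          axial_radius_um=0.5)
        proto = LaserProtocol(mode="pulsed", repetition_frequency_hz=1.0,
                              pulse_length_ms=0.2, session_duration_s=1.0)
        tau = proto.pulse_length_ms * 1e-3
        P = proto.absorbed_power_w
        for r_um in (2.0, 5.0, 10.0):
            direct, _ = quad(
                lambda tp: P * heat_kernel(r_um * 1e-6, tau - tp, 1.0, water),
                0.0, tau, limit=200,
            )
            mine = lateral_profile(proto, water, src, np.array([r_um]),
                                   "in_pulse_peak")[0]
            assert mine == pytest.approx(direct, rel=5e-3)

    def test_in_pulse_dominates_inter_pulse_pointwise(self, water, spheroid_source,
                                                      khz_protocol):
        grid = _xz_grid(extent_um=12.0, n=25)
        f_in = pulse_train_field(khz_protocol, water, spheroid_source, grid,
                                 "in_pulse_peak")
        f_out = pulse_train_field(khz_protocol, water, spheroid_source, grid,
                                  "inter_pulse")
        assert np.all(f_in.values >= f_out.values - 1e-12)
        assert f_in.phase_label == "in_pulse_peak"

    def test_inter_pulse_profile_nearly_uniform(self, water, spheroid_source,
                                                khz_protocol):
        """Between 1 kHz / 0.2 ms pulses the profile flattens: F < 0.25."""
        r = np.linspace(0.0, 12.0, 121)
        prof_in = lateral_profile(khz_protocol, water, spheroid_source, r,
                                  "in_pulse_peak")
        prof_out = lateral_profile(khz_protocol, water, spheroid_source, r,
                                   "inter_pulse")
        flatness = (prof_out.max() - prof_out.min()) / prof_in.max()
        assert flatness < 0.25

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_fields_scale_linearly_with_power(self, scale):
        water = Medium.water()
        src = SourceModel()
        proto = LaserProtocol()
        r = np.array([0.0, 1.0, 3.0, 8.0])
        base = lateral_profile(proto, water, src, r, "in_pulse_peak")
        scaled = lateral_profile(proto.with_incident_power(
            proto.incident_power_mw * scale), water, src, r, "in_pulse_peak")
        np.testing.assert_allclose(scaled, base * scale, rtol=1e-9)

    def test_point_source_field_is_radially_symmetric(self, water):
        src = SourceModel(geometry="point", lateral_radius_um=0.5,
                          axial_radius_um=0.5)
        proto = LaserProtocol()
        grid = _xz_grid(extent_um=6.0, n=25)
        f = pulse_train_field(proto, water, src, grid, "in_pulse_peak")
        # reflections through the focus leave the field unchanged
        np.testing.assert_allclose(f.values, f.values[::-1, :, :], rtol=1e-9)
        np.testing.assert_allclose(f.values, f.values[:, :, ::-1], rtol=1e-9)
        # x and z axes are interchangeable for an isotropic point source
        np.testing.assert_allclose(f.values[12, 0, :], f.values[:, 0, 12], rtol=1e-9)

    def test_time_average_equals_duty_scaled_cw(self, water, isotropic_source,
                                                khz_protocol):
        r = np.array([1.0, 3.0, 8.0])
        avg = lateral_profile(khz_protocol, water, isotropic_source, r,
                              "time_average")
        cw = cw_steady_state(r * 1e-6,
                             khz_protocol.absorbed_power_w * khz_protocol.duty_cycle,
                             water, isotropic_source)
        np.testing.assert_allclose(avg, cw, rtol=2e-3)


# ---------------------------------------------------------------------------
# normalization and isotherms
# ---------------------------------------------------------------------------


class TestNormalizeToPeak:
    def test_linearity_and_limits(self, water, spheroid_source, khz_protocol):
        p1 = normalize_to_peak(khz_protocol, water, spheroid_source, 36.5)
        p2 = normalize_to_peak(khz_protocol, water, spheroid_source, 50.0)
        # doubling (target - ambient): 13.5 -> 27 doubles the power exactly
        assert p2.incident_power_mw == pytest.approx(2 * p1.incident_power_mw, rel=1e-9)
        assert normalize_to_peak(khz_protocol, water, spheroid_source,
                                 23.0).incident_power_mw == 0.0
        with pytest.raises(ValueError, match="below ambient"):
            normalize_to_peak(khz_protocol, water, spheroid_source, 20.0)

    def test_peak_50_at_ambient_23_gives_delta_27(self, water, spheroid_source,
                                                  khz_protocol):
        p = normalize_to_peak(khz_protocol, water, spheroid_source, 50.0)
        assert peak_delta_t(p, water, spheroid_source) == pytest.approx(27.0, rel=1e-9)


def _gaussian_field(peak_dt=27.0, w_um=3.0, wz_um=6.0, ambient=23.0,
                    extent=12.0, n=121):
    axis = np.linspace(-extent, extent, n)
    x = axis[None, None, :]
    y = np.zeros(1)[None, :, None]
    z = axis[:, None, None]
    vals = peak_dt * np.exp(-(x**2 + y**2) / w_um**2 - z**2 / wz_um**2)
    return TemperatureField(axis, np.zeros(1), axis, vals, ambient, "in_pulse_peak")


class TestIsothermExtent:
    def test_threshold_above_peak_gives_empty_isotherm(self):
        field = _gaussian_field()
        rep = isotherm_extent(field, 99.0)
        assert rep.lateral_radius_um == 0.0
        assert rep.axial_radius_um == 0.0
        assert rep.heated_volume_um3 == 0.0

    def test_gaussian_field_matches_closed_form(self):
        """For dT = dTp*exp(-r^2/w^2) the radius is w*sqrt(ln(dTp/dTthr))."""
        field = _gaussian_field(peak_dt=27.0, w_um=3.0, wz_um=6.0, ambient=23.0)
        rep = isotherm_extent(field, 35.0)
        cell = 24.0 / 120
        expected_lat = 3.0 * math.sqrt(math.log(27.0 / 12.0))
        expected_ax = 6.0 * math.sqrt(math.log(27.0 / 12.0))
        assert abs(rep.lateral_radius_um - expected_lat) < cell
        assert abs(rep.axial_radius_um - expected_ax) < cell

    def test_inverse_distance_field_radius_2p25_source_radii(self):
        """1/r field with peak dT 27 at radius a, threshold dT 12 -> r = 2.25a."""
        a = 2.0
        axis = np.linspace(-10.0, 10.0, 201)
        x = axis[None, None, :]
        z = axis[:, None, None]
        r = np.sqrt(x**2 + z**2)
        vals = 27.0 * a / np.maximum(r, a)
        field = TemperatureField(axis, np.zeros(1), axis, vals, 23.0, "steady_state")
        rep = isotherm_extent(field, 35.0)
        assert rep.lateral_radius_um == pytest.approx(2.25 * a, abs=0.1)

    @given(thr=st.floats(min_value=24.0, max_value=49.0))
    def test_radius_monotone_decreasing_in_threshold(self, thr):
        field = _gaussian_field()
        r1 = isotherm_extent(field, thr).lateral_radius_um
        r2 = isotherm_extent(field, thr + 1.0).lateral_radius_um
        assert r1 >= r2

    def test_crossing_radius_interpolates_subgrid(self):
        r = np.array([0.0, 1.0, 2.0, 3.0])
        v = np.array([10.0, 8.0, 4.0, 2.0])
        assert crossing_radius(r, v, 6.0) == pytest.approx(1.5)
        assert crossing_radius(r, v, 11.0) == 0.0


class TestParameterSweep:
    def test_rows_and_monotonicity(self, water, spheroid_source, khz_protocol):
        df = parameter_sweep(
            khz_protocol, water, spheroid_source,
            powers_mw=[100.0, 200.0], frequencies_hz=[1000.0],
            duty_cycles=[0.2, 1.0],
        )
        assert len(df) == 4
        # peak dT strictly increasing in power at fixed timing
        low = df[(df.duty_cycle == 0.2) & (df.power_mw == 100.0)].peak_dT_C.iloc[0]
        high = df[(df.duty_cycle == 0.2) & (df.power_mw == 200.0)].peak_dT_C.iloc[0]
        assert high == pytest.approx(2 * low, rel=1e-9)

    def test_duty_one_row_matches_cw(self, water, isotropic_source, khz_protocol):
        df = parameter_sweep(
            khz_protocol, water, isotropic_source,
            powers_mw=[150.0], frequencies_hz=[1000.0], duty_cycles=[1.0],
        )
        cw = LaserProtocol(mode="cw", repetition_frequency_hz=None,
                           pulse_length_ms=None, incident_power_mw=150.0)
        assert df.peak_dT_C.iloc[0] == pytest.approx(
            peak_delta_t(cw, water, isotropic_source), rel=0.01
        )

    def test_normalized_radius_nondecreasing_in_duty(self, water, spheroid_source,
                                                     khz_protocol):
        """At matched 50 C peak, shorter duty confines the isotherm more."""
        radii = []
        for duty in (0.05, 0.2, 0.5, 1.0):
            if duty >= 1.0:
                proto = LaserProtocol(mode="cw", repetition_frequency_hz=None,
                                      pulse_length_ms=None)
            else:
                proto = LaserProtocol(mode="pulsed", repetition_frequency_hz=1000.0,
                                      pulse_length_ms=duty)
            proto = normalize_to_peak(proto, water, spheroid_source, 50.0)
            radii.append(lateral_isotherm_radius(proto, water, spheroid_source, 35.0))
        assert all(b >= a - 1e-9 for a, b in zip(radii, radii[1:]))

    def test_empty_grid_rejected(self, water, spheroid_source, khz_protocol):
        with pytest.raises(ValueError, match="non-empty"):
            parameter_sweep(khz_protocol, water, spheroid_source, [], [1000.0], [0.2])


class TestCoverslipMirror:
    def test_mirror_sink_suppresses_field_near_boundary(self, water,
                                                        isotropic_source,
                                                        cw_protocol):
        """The half-space mirror-sink mode pins the temperature rise to zero
        at the stated plane and reduces it everywhere in between."""
        axis = np.linspace(-8.0, 8.0, 33)
        grid = (np.zeros(1), np.zeros(1), axis)
        free = pulse_train_field(cw_protocol, water, isotropic_source, grid)
        sunk = pulse_train_field(cw_protocol, water, isotropic_source, grid,
                                 coverslip_mirror_um=8.0)
        assert np.all(sunk.values <= free.values + 1e-12)
        assert sunk.values[-1, 0, 0] == pytest.approx(0.0, abs=1e-9)
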