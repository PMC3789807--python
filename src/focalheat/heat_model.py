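"""Laser-induced temperature fields for focused CW and pulsed heating in water.

A tightly focused infrared beam (1480 nm, strongly absorbed by water) acts as a
micron-scale heat source inside an effectively infinite aqueous medium.  Two
regimes matter for single-cell heat shock:

* **Continuous-wave (CW)** heating reaches a quasi steady state in which the
  temperature rise outside the source falls off as the inverse of the distance
  to the focus, ``dT(r) = P / (4*pi*k*r)`` — a slow decay that heats a large
  neighbourhood.

* **Pulsed** heating deposits energy in brief pulses.  Each pulse produces a
  sharply peaked, nearly Gaussian transient (the heat-equation Green's
  function, spatial width ``sqrt(4*alpha*t)``) that diffuses away between
  pulses, so the time-averaged background stays low and the hot region is
  confined to the focus.

Everything here is linear in absorbed power, so fields superpose over the pulse
history and rescale exactly with power.  Temperature fields are computed by
superposing closed-form kernel integrals (isotropic Gaussian or point sources)
or low-order quadrature (spheroidal sources), truncating the pulse history once
it has converged and accounting for the remaining history with a duty-scaled
continuous tail.

Unit conventions: user-facing lengths are in micrometres, times in
milliseconds, powers in milliwatts and temperatures in degrees Celsius; the
low-level kernels (`heat_kernel`, `cw_steady_state`) use SI units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import erf

__all__ = [
    "Medium",
    "SourceModel",
    "LaserProtocol",
    "TemperatureField",
    "IsothermReport",
    "heat_kernel",
    "cw_steady_state",
    "pulse_train_field",
    "gated_time_average",
    "normalize_to_peak",
    "isotherm_extent",
    "parameter_sweep",
    "lateral_profile",
    "crossing_radius",
]

UM = 1e-6
MS = 1e-3
MW = 1e-3
_SQRT_PI = math.sqrt(math.pi)

PHASE_LABELS = ("in_pulse_peak", "inter_pulse", "steady_state", "time_average")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Medium:
    """Thermal and optical constants of the heated aqueous medium.

    Defaults are literature values for water near room temperature:
    k = 0.6 W/m/K, rho*c = 4.18e6 J/m^3/K (alpha ~ 1.43e-7 m^2/s) and an
    absorption coefficient of 2.3e3 1/m at 1480 nm.
    """

    thermal_conductivity: float = 0.6  # W / m / K
    volumetric_heat_capacity: float = 4.18e6  # J / m^3 / K
    thermal_diffusivity: float | None = None  # m^2 / s; derived if omitted
    absorption_coefficient: float = 2.3e3  # 1/m at 1480 nm

    def __post_init__(self) -> None:
        if self.thermal_conductivity <= 0 or self.volumetric_heat_capacity <= 0:
            raise ValueError("medium constants must be strictly positive")
        if self.absorption_coefficient <= 0:
            raise ValueError("absorption coefficient must be strictly positive")
        derived = self.thermal_conductivity / self.volumetric_heat_capacity
        if self.thermal_diffusivity is None:
            object.__setattr__(self, "thermal_diffusivity", derived)
        else:
            if self.thermal_diffusivity <= 0:
                raise ValueError("thermal diffusivity must be strictly positive")
            if abs(self.thermal_diffusivity - derived) > 1e-9 * derived:
                raise ValueError(
                    "thermal_diffusivity inconsistent with k / (rho*c): "
                    f"{self.thermal_diffusivity!r} vs {derived!r}"
                )

    @classmethod
    def water(cls) -> "Medium":
        return cls()


@dataclass(frozen=True)
class SourceModel:
    """Geometry of the focal heat source.

    ``gaussian_spheroid`` deposits heat with Gaussian density
    exp(-(x^2+y^2)/w0^2 - z^2/wz^2); ``point`` is the idealized point source
    (its radii are used only to cap the on-axis singularity).
    Defaults w0 = 1 um, wz = 2 um correspond to a high-NA (~1.3) focus.
    """

    geometry: str = "gaussian_spheroid"  # "point" | "gaussian_spheroid"
    lateral_radius_um: float = 1.0
    axial_radius_um: float = 2.0

    def __post_init__(self) -> None:
        if self.geometry not in ("point", "gaussian_spheroid"):
            raise ValueError(f"unknown source geometry {self.geometry!r}")
        if self.lateral_radius_um <= 0 or self.axial_radius_um <= 0:
            raise ValueError("source radii must be strictly positive")
        if self.geometry == "gaussian_spheroid" and (
            self.axial_radius_um < self.lateral_radius_um
        ):
            raise ValueError("focused beam is axially elongated: wz >= w0 required")

    @property
    def is_isotropic(self) -> bool:
        return (
            self.geometry == "gaussian_spheroid"
            and self.axial_radius_um == self.lateral_radius_um
        )

    @property
    def effective_radius_um(self) -> float:
        """Isotropic radius with the same second moment, for far-field tails."""
        w0, wz = self.lateral_radius_um, self.axial_radius_um
        return math.sqrt((2.0 * w0**2 + wz**2) / 3.0)


@dataclass(frozen=True)
class LaserProtocol:
    """Illumination mode and timing/power parameters of a heating session."""

    mode: str = "pulsed"  # "cw" | "pulsed"
    incident_power_mw: float = 220.0
    absorbed_fraction: float = 0.0046
    repetition_frequency_hz: float | None = 1000.0
    pulse_length_ms: float | None = 0.2
    session_duration_s: float = 360.0
    ambient_temperature_c: float = 23.0

    def __post_init__(self) -> None:
        if self.mode not in ("cw", "pulsed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.incident_power_mw < 0:
            raise ValueError("incident power must be non-negative")
        if not 0.0 <= self.absorbed_fraction <= 1.0:
            raise ValueError("absorbed fraction must lie in [0, 1]")
        if self.session_duration_s <= 0:
            raise ValueError("session duration must be positive")
        if not 0.0 <= self.ambient_temperature_c <= 60.0:
            raise ValueError("ambient temperature outside physical range 0-60 C")
        if self.mode == "pulsed":
            if not self.repetition_frequency_hz or self.repetition_frequency_hz <= 0:
                raise ValueError("pulsed mode requires a positive repetition frequency")
            if not self.pulse_length_ms or self.pulse_length_ms <= 0:
                raise ValueError("pulsed mode requires a positive pulse length")
            if self.duty_cycle > 1.0 + 1e-12:
                raise ValueError(
                    f"duty cycle {self.duty_cycle:.3f} exceeds 1 "
                    "(pulse_length * frequency must be <= 1)"
                )

    @property
    def duty_cycle(self) -> float:
        if self.mode == "cw":
            return 1.0
        return self.pulse_length_ms * MS * self.repetition_frequency_hz

    @property
    def period_ms(self) -> float:
        if self.mode == "cw":
            raise ValueError("CW protocol has no pulse period")
        return 1e3 / self.repetition_frequency_hz

    @property
    def absorbed_power_w(self) -> float:
        return self.incident_power_mw * MW * self.absorbed_fraction

    def with_incident_power(self, power_mw: float) -> "LaserProtocol":
        return replace(self, incident_power_mw=power_mw)

    def with_ambient(self, ambient_c: float) -> "LaserProtocol":
        return replace(self, ambient_temperature_c=ambient_c)


@dataclass
class TemperatureField:
    """Sampled temperature rise over a regular grid, at a stated pulse phase.

    ``values`` has shape (nz, ny, nx); coordinates are micrometres and centred
    on the laser focus (the optical axis is z).
    """

    x_um: np.ndarray
    y_um: np.ndarray
    z_um: np.ndarray
    values: np.ndarray  # delta T in C, shape (nz, ny, nx)
    ambient_c: float
    phase_label: str

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.z_um.size, self.y_um.size, self.x_um.size)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != grid {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("temperature field contains non-finite values")
        if self.values.min() < -1e-9:
            raise ValueError("heating-only source cannot produce negative delta T")
        # tolerate tiny negative round-off
        np.maximum(self.values, 0.0, out=self.values)
        if not 0.0 <= self.ambient_c <= 60.0:
            raise ValueError("ambient temperature outside physical range 0-60 C")

    @property
    def peak_delta_t(self) -> float:
        return float(self.values.max())

    @property
    def peak_index(self) -> tuple[int, int, int]:
        """Index of the field maximum; a flat-topped peak (e.g. a capped
        profile) resolves to the centroid of the plateau."""
        top = self.values >= self.values.max() * (1.0 - 1e-12)
        idx = np.nonzero(top)
        return tuple(int(round(float(np.mean(ax)))) for ax in idx)

    def absolute(self) -> np.ndarray:
        return self.values + self.ambient_c

    def scaled(self, factor: float) -> "TemperatureField":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return TemperatureField(
            self.x_um, self.y_um, self.z_um, self.values * factor,
            self.ambient_c, self.phase_label,
        )


@dataclass(frozen=True)
class IsothermReport:
    """Extent of the region whose absolute temperature exceeds a threshold."""

    threshold_c: float
    lateral_radius_um: float
    axial_radius_um: float
    heated_volume_um3: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.lateral_radius_um < 0 or self.axial_radius_um < 0:
            raise ValueError("isotherm radii must be non-negative")
        volume = (
            4.0 / 3.0 * math.pi * self.lateral_radius_um**2 * self.axial_radius_um
        )
        if self.heated_volume_um3 is None:
            object.__setattr__(self, "heated_volume_um3", volume)
        elif not math.isclose(self.heated_volume_um3, volume, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("heated volume inconsistent with ellipsoid model")


# ---------------------------------------------------------------------------
# closed-form kernels (SI units)
# ---------------------------------------------------------------------------


def heat_kernel(r_m, t_s: float, energy_j: float, medium: Medium):
    """Instantaneous point-release Green's function of the heat equation.

    dT(r, t) = E / (rho*c * (4*pi*alpha*t)^{3/2}) * exp(-r^2 / (4*alpha*t)),
    the Gaussian temperature transient produced by depositing energy E at the
    origin at t = 0.  Arguments in SI units (m, s, J); returns dT in C.
    """
    if t_s <= 0:
        raise ValueError("heat kernel requires elapsed time t > 0")
    if energy_j < 0:
        raise ValueError("deposited energy must be non-negative")
    r = np.asarray(r_m, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    alpha = medium.thermal_diffusivity
    rho_c = medium.volumetric_heat_capacity
    width2 = 4.0 * alpha * t_s
    norm = energy_j / (rho_c * (math.pi * width2) ** 1.5)
    out = norm * np.exp(-(r**2) / width2)
    return out if out.ndim else float(out)


def _erf_over_r(r, u):
    """erf(r/u)/r with the analytic small-r limit 2/(sqrt(pi)*u).

    ``u = 0`` denotes an un-diffused point release, for which the ratio is 1/r.
    """
    r = np.asarray(r, dtype=float)
    if u == 0.0:
        with np.errstate(divide="ignore"):
            return np.where(r > 0, 1.0 / np.where(r > 0, r, 1.0), np.inf)
    small = r < 1e-9 * u
    r_safe = np.where(small, 1.0, r)
    out = np.where(small, 2.0 / (_SQRT_PI * u), erf(r_safe / u) / r_safe)
    return out


def cw_steady_state(r_m, absorbed_power_w: float, medium: Medium,
                    source: SourceModel | None = None):
    """Steady-state temperature rise of continuous focal heating.

    For a point source dT(r) = P / (4*pi*k*r) — the inverse-distance law.
    For a Gaussian source of isotropic-equivalent radius w the exact steady
    solution is dT(r) = P * erf(r/w) / (4*pi*k*r), which matches the
    inverse-distance law outside the source and stays finite at the origin.
    SI inputs (m, W); returns dT in C.
    """
    if absorbed_power_w < 0:
        raise ValueError("absorbed power must be non-negative")
    k = medium.thermal_conductivity
    r = np.asarray(r_m, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    if source is None or source.geometry == "point":
        if source is None:
            if np.any(r == 0):
                raise ValueError(
                    "point-source steady state is singular at r = 0; "
                    "provide a SourceModel to cap at the source radius"
                )
            r_eff = r
        else:
            r_eff = np.maximum(r, source.lateral_radius_um * UM)
        out = absorbed_power_w / (4.0 * math.pi * k * r_eff)
    else:
        w = source.effective_radius_um * UM
        out = absorbed_power_w / (4.0 * math.pi * k) * _erf_over_r(r, w)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# pulse-train superposition
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = leggauss(8)


def _interval_isotropic(power_w, medium, w_m, r_m, s0, s1):
    """Heating interval (ages s0..s1 s) of an isotropic Gaussian source.

    Closed form: dT = P/(4*pi*k) * [erf(r/u0) - erf(r/u1)]/r with
    u = sqrt(w^2 + 4*alpha*s).
    """
    alpha = medium.thermal_diffusivity
    k = medium.thermal_conductivity
    u0 = math.sqrt(w_m**2 + 4.0 * alpha * s0)
    u1 = math.sqrt(w_m**2 + 4.0 * alpha * s1)
    return power_w / (4.0 * math.pi * k) * (_erf_over_r(r_m, u0) - _erf_over_r(r_m, u1))


def _interval_spheroid(power_w, medium, w0_m, wz_m, rho2_m2, z2_m2, s0, s1):
    """Heating interval of an anisotropic Gaussian (spheroidal) source.

    Substituting v = 1/sqrt(w0^2 + 4*alpha*s) turns the time integral into

        dT = P / (2*alpha*rho*c*pi^{3/2}) *
             int_{v1}^{v0} exp(-rho^2 v^2 - z^2 v^2/(1+D v^2)) / sqrt(1+D v^2) dv

    with D = wz^2 - w0^2, which is Gaussian-like in v and integrates well with
    geometrically-paneled Gauss-Legendre quadrature.
    """
    alpha = medium.thermal_diffusivity
    rho_c = medium.volumetric_heat_capacity
    v0 = 1.0 / math.sqrt(w0_m**2 + 4.0 * alpha * s0)
    v1 = 1.0 / math.sqrt(w0_m**2 + 4.0 * alpha * s1)
    delta = wz_m**2 - w0_m**2
    pref = power_w / (2.0 * alpha * rho_c * math.pi**1.5)
    n_panels = max(1, min(40, int(math.ceil(math.log2(v0 / v1)))))
    edges = v1 * (v0 / v1) ** (np.arange(n_panels + 1) / n_panels)
    acc = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        vm = 0.5 * (a + b)
        vh = 0.5 * (b - a)
        for x, wgt in zip(_GL_NODES, _GL_WEIGHTS):
            v = vm + vh * x
            dv2 = 1.0 + delta * v * v
            f = np.exp(-rho2_m2 * v * v - z2_m2 * v * v / dv2) / math.sqrt(dv2)
            acc = acc + wgt * vh * f
    return pref * acc


def _interval_delta_t(power_w, medium, source, rho2, z2, r, s0, s1):
    """Temperature contribution of one continuous-heating age interval."""
    if source.geometry == "point":
        r_eff = np.maximum(r, source.lateral_radius_um * UM)
        alpha = medium.thermal_diffusivity
        k = medium.thermal_conductivity
        u0 = math.sqrt(4.0 * alpha * s0)
        u1 = math.sqrt(4.0 * alpha * s1)
        return power_w / (4.0 * math.pi * k) * (
            _erf_over_r(r_eff, u0) - _erf_over_r(r_eff, u1)
        )
    w0 = source.lateral_radius_um * UM
    wz = source.axial_radius_um * UM
    if source.is_isotropic:
        return _interval_isotropic(power_w, medium, w0, r, s0, s1)
    return _interval_spheroid(power_w, medium, w0, wz, rho2, z2, s0, s1)


def _tail_delta_t(power_w, medium, source, r, s0, s1):
    """Far-history contribution, treated as an isotropic-equivalent source."""
    w_eff = source.effective_radius_um * UM if source.geometry != "point" else 0.0
    if source.geometry == "point":
        r = np.maximum(r, source.lateral_radius_um * UM)
    return _interval_isotropic(power_w, medium, w_eff, r, s0, s1)


def _pulse_schedule(protocol: LaserProtocol, phase_ms: float):
    """Explicit pulse age-intervals plus duty-scaled tail for a pulsed protocol.

    Returns (intervals, tail) where intervals is a list of (s0, s1) ages in
    seconds at full power and tail is None or (s0, s1) at duty-scaled power.
    Truncation: explicit pulses are added until one more changes the focal
    in-pulse peak by < 0.1% relative; the remaining history is the tail.
    """
    tau = protocol.pulse_length_ms * MS
    period = 1.0 / protocol.repetition_frequency_hz
    phase_s = phase_ms * MS
    if not 0.0 <= phase_s <= period + 1e-15:
        raise ValueError(f"phase {phase_ms} ms outside pulse cycle of {period / MS} ms")
    n_total = max(1, int(math.floor(protocol.session_duration_s / period + 1e-9)))
    intervals: list[tuple[float, float]] = []
    # current cycle's pulse (may be partially elapsed, or not started yet)
    if phase_s > 0:
        if phase_s < tau:
            intervals.append((0.0, phase_s))
        else:
            intervals.append((phase_s - tau, phase_s))
    for k in range(1, n_total):
        intervals.append((phase_s + k * period - tau, phase_s + k * period))
    return intervals, n_total, period, tau, phase_s


def _converged_interval_count(protocol, medium, source, intervals):
    """Number of explicit pulses needed for 0.1%-converged focal peak."""
    zero = np.zeros(1)
    total = 0.0
    for i, (s0, s1) in enumerate(intervals):
        contrib = float(
            _interval_delta_t(
                protocol.absorbed_power_w, medium, source, zero, zero, zero, s0, s1
            )[0]
        )
        total += contrib
        if i >= 2 and total > 0 and contrib < 1e-3 * total:
            return i + 1
    return len(intervals)


def _delta_t_points(protocol, medium, source, rho2, z2, r, phase):
    """Quasi-steady temperature rise at arbitrary points (SI squared coords)."""
    power = protocol.absorbed_power_w
    if power == 0.0:
        return np.zeros(np.broadcast(rho2, z2).shape)
    session = protocol.session_duration_s
    continuous = protocol.mode == "cw" or protocol.duty_cycle >= 1.0 - 1e-9

    if continuous or phase == "time_average":
        eff_power = power if continuous else power * protocol.duty_cycle
        # near-history handled exactly; far history as isotropic point tail
        if source.geometry == "gaussian_spheroid" and not source.is_isotropic:
            alpha = medium.thermal_diffusivity
            wz = source.axial_radius_um * UM
            s_cut = min(session, 100.0 * wz**2 / (4.0 * alpha))
            out = _interval_delta_t(eff_power, medium, source, rho2, z2, r, 0.0, s_cut)
            if s_cut < session:
                out = out + _tail_delta_t(eff_power, medium, source, r, s_cut, session)
            return out
        return _interval_delta_t(eff_power, medium, source, rho2, z2, r, 0.0, session)

    if phase == "steady_state":
        raise ValueError("steady_state phase applies to CW protocols only")
    if phase == "in_pulse_peak":
        phase_ms = protocol.pulse_length_ms
    elif phase == "inter_pulse":
        phase_ms = protocol.period_ms
    else:
        phase_ms = float(phase)

    intervals, n_total, period, tau, phase_s = _pulse_schedule(protocol, phase_ms)
    if not intervals:
        # phase 0 with no prior pulses: no heating yet
        if n_total <= 1:
            return np.zeros(np.broadcast(rho2, z2).shape)
    n_keep = _converged_interval_count(protocol, medium, source, intervals)
    if n_keep >= 10000:
        raise RuntimeError("pulse-train superposition failed to converge")
    out = 0.0
    for s0, s1 in intervals[:n_keep]:
        out = out + _interval_delta_t(power, medium, source, rho2, z2, r, s0, s1)
    if n_keep < len(intervals):
        s_tail0 = intervals[n_keep][0]
        s_tail1 = phase_s + n_total * period
        out = out + _tail_delta_t(
            power * protocol.duty_cycle, medium, source, r, s_tail0, s_tail1
        )
    return np.asarray(out)


def _grid_coords(grid):
    x_um, y_um, z_um = (np.atleast_1d(np.asarray(g, dtype=float)) for g in grid)
    x = x_um[None, None, :] * UM
    y = y_um[None, :, None] * UM
    z = z_um[:, None, None] * UM
    rho2 = x**2 + y**2
    z2 = z**2 + np.zeros_like(rho2)
    r = np.sqrt(rho2 + z2)
    return x_um, y_um, z_um, rho2, z2, r


def pulse_train_field(
    protocol: LaserProtocol,
    medium: Medium,
    source: SourceModel,
    grid: Sequence[np.ndarray],
    phase: str | float = "in_pulse_peak",
    *,
    coverslip_mirror_um: float | None = None,
) -> TemperatureField:
    """Quasi-steady temperature field of a (pulsed or CW) heating session.

    ``grid`` is a tuple of 1-D coordinate arrays (x_um, y_um, z_um) centred on
    the focus.  ``phase`` is one of the standard labels (``in_pulse_peak``,
    ``inter_pulse``, ``time_average``, ``steady_state``) or a numeric phase in
    milliseconds within the pulse cycle.  For accuracy the grid spacing should
    not exceed half the lateral source radius near the focus.

    ``coverslip_mirror_um`` switches on a half-space mirror-sink boundary: an
    ideal heat sink at the stated z plane, mimicking coverslip heat-sinking.
    Default is an infinite medium.
    """
    x_um, y_um, z_um, rho2, z2, r = _grid_coords(grid)
    values = _delta_t_points(protocol, medium, source, rho2, z2, r, phase)
    values = np.broadcast_to(values, (z_um.size, y_um.size, x_um.size)).copy()
    if coverslip_mirror_um is not None:
        z_img = (2.0 * coverslip_mirror_um - z_um[:, None, None]) * UM
        z2_img = z_img**2 + np.zeros_like(rho2)
        r_img = np.sqrt(rho2 + z2_img)
        mirror = _delta_t_points(protocol, medium, source, rho2, z2_img, r_img, phase)
        values = np.maximum(values - np.broadcast_to(mirror, values.shape), 0.0)
    if protocol.mode == "cw" or protocol.duty_cycle >= 1.0 - 1e-9:
        label = "time_average" if phase == "time_average" else "steady_state"
    else:
        label = phase if isinstance(phase, str) else f"phase_{float(phase):g}ms"
    return TemperatureField(
        x_um, y_um, z_um, values, protocol.ambient_temperature_c, label
    )


def gated_time_average(
    protocol: LaserProtocol,
    medium: Medium,
    source: SourceModel,
    grid: Sequence[np.ndarray],
    gate_start_ms: float,
    gate_end_ms: float,
    n_nodes: int = 8,
) -> TemperatureField:
    """Time-average of the quasi-steady field over a sub-window of the cycle.

    Models phase-gated excitation: the camera integrates fluorescence only
    while the excitation LED is on, so the measured intensity reflects the
    time-mean of the (linear-in-T) fluorescence over the gate window.  Because
    the fluorescence law is linear in temperature, averaging intensity and
    averaging temperature commute exactly here.
    """
    if protocol.mode == "cw":
        raise ValueError("gated acquisition requires a pulsed protocol")
    if not gate_end_ms > gate_start_ms:
        raise ValueError("gate window must have positive length")
    if gate_start_ms < 0 or gate_end_ms > protocol.period_ms + 1e-12:
        raise ValueError("gate window must lie within the pulse cycle")
    nodes, weights = leggauss(n_nodes)
    # the field varies smoothly within the pulse and between pulses but has a
    # kink at the pulse edge: integrate each segment separately
    tau = protocol.pulse_length_ms
    edges = sorted({gate_start_ms, gate_end_ms} |
                   ({tau} if gate_start_ms < tau < gate_end_ms else set()))
    x_um, y_um, z_um, rho2, z2, r = _grid_coords(grid)
    acc = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        for x, wgt in zip(nodes, weights):
            phi = mid + half * x
            acc = acc + wgt * half * _delta_t_points(
                protocol, medium, source, rho2, z2, r, phi
            )
    acc = acc / (gate_end_ms - gate_start_ms)
    values = np.broadcast_to(acc, (z_um.size, y_um.size, x_um.size)).copy()
    return TemperatureField(
        x_um, y_um, z_um, values, protocol.ambient_temperature_c, "time_average"
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def peak_delta_t(protocol, medium, source, phase: str | float | None = None) -> float:
    """Focal temperature rise at the hottest phase of the cycle."""
    if phase is None:
        phase = "steady_state" if protocol.mode == "cw" else "in_pulse_peak"
    zero = np.zeros(1)
    return float(
        _delta_t_points(protocol, medium, source, zero, zero, zero, phase)[0]
    )


def normalize_to_peak(
    protocol: LaserProtocol,
    medium: Medium,
    source: SourceModel,
    peak_target_c: float,
) -> LaserProtocol:
    """Rescale power so the peak absolute temperature equals ``peak_target_c``.

    The heat equation is linear in absorbed power, so a single field evaluation
    and a scalar rescale suffice.  A target equal to ambient returns zero
    power; a target below ambient is a domain error (heating only).
    """
    ambient = protocol.ambient_temperature_c
    if peak_target_c < ambient:
        raise ValueError("peak target below ambient: heating-only source")
    if peak_target_c == ambient:
        return protocol.with_incident_power(0.0)
    if protocol.incident_power_mw == 0 or protocol.absorbed_fraction == 0:
        raise ValueError("cannot normalize a protocol with zero absorbed power")
    current = peak_delta_t(protocol, medium, source)
    scale = (peak_target_c - ambient) / current
    return protocol.with_incident_power(protocol.incident_power_mw * scale)


def crossing_radius(coords_um: np.ndarray, values: np.ndarray, threshold: float) -> float:
    """Distance from ``coords_um[0]`` at which ``values`` first drops below
    ``threshold``, by monotone bracketing with linear sub-grid interpolation.

    ``values[0]`` is the peak sample; returns 0.0 if already below threshold
    and the last coordinate (with a warning) if the profile never crosses.
    """
    coords_um = np.asarray(coords_um, dtype=float)
    values = np.asarray(values, dtype=float)
    if values[0] < threshold:
        return 0.0
    below = np.nonzero(values < threshold)[0]
    if below.size == 0:
        warnings.warn("isotherm does not close within the sampled grid")
        return float(abs(coords_um[-1] - coords_um[0]))
    j = int(below[0])
    v0, v1 = values[j - 1], values[j]
    c0, c1 = coords_um[j - 1], coords_um[j]
    frac = (v0 - threshold) / (v0 - v1) if v0 != v1 else 0.0
    return float(abs(c0 + frac * (c1 - c0) - coords_um[0]))


def _axis_radius(coords, profile, peak_idx, threshold):
    radii = []
    if peak_idx < profile.size - 1:
        radii.append(crossing_radius(coords[peak_idx:], profile[peak_idx:], threshold))
    if peak_idx > 0:
        radii.append(
            crossing_radius(coords[peak_idx::-1], profile[peak_idx::-1], threshold)
        )
    return float(np.mean(radii)) if radii else 0.0


def isotherm_extent(field: TemperatureField, threshold_c: float) -> IsothermReport:
    """Lateral and axial radii of the supra-threshold isotherm.

    Radii are found along the principal axes through the field peak by
    monotone root bracketing with linear interpolation; the heated volume uses
    the ellipsoid model 4/3*pi*rl^2*ra.  A threshold above the peak gives zero
    radii (an empty isotherm, not an error).
    """
    abs_t = field.absolute()
    iz, iy, ix = field.peak_index
    peak = abs_t[iz, iy, ix]
    if threshold_c > peak:
        return IsothermReport(threshold_c, 0.0, 0.0)
    lateral = _axis_radius(field.x_um, abs_t[iz, iy, :], ix, threshold_c)
    if field.y_um.size >= 3:
        lat_y = _axis_radius(field.y_um, abs_t[iz, :, ix], iy, threshold_c)
        lateral = 0.5 * (lateral + lat_y)
    if field.z_um.size >= 3:
        axial = _axis_radius(field.z_um, abs_t[:, iy, ix], iz, threshold_c)
    else:
        raise ValueError(
            "axial isotherm radius requires a field with z extent (nz >= 3)"
        )
    return IsothermReport(threshold_c, lateral, axial)


def lateral_profile(
    protocol: LaserProtocol,
    medium: Medium,
    source: SourceModel,
    r_um: np.ndarray,
    phase: str | float = "in_pulse_peak",
) -> np.ndarray:
    """Temperature rise along the lateral (x) axis through the focus."""
    r_um = np.asarray(r_um, dtype=float)
    rho2 = (r_um * UM) ** 2
    z2 = np.zeros_like(rho2)
    r = np.abs(r_um) * UM
    return np.asarray(
        _delta_t_points(protocol, medium, source, rho2, z2, r, phase), dtype=float
    )


def lateral_isotherm_radius(
    protocol, medium, source, threshold_c: float, *,
    phase: str | float | None = None,
    spacing_um: float | None = None,
    extent_um: float | None = None,
) -> float:
    """Lateral radius of the supra-threshold region on a dense 1-D axis."""
    if phase is None:
        phase = "steady_state" if protocol.mode == "cw" else "in_pulse_peak"
    if spacing_um is None:
        spacing_um = source.lateral_radius_um / 16.0
    if extent_um is None:
        extent_um = max(40.0 * source.lateral_radius_um, 20.0)
    r = np.arange(0.0, extent_um + spacing_um, spacing_um)
    profile = lateral_profile(protocol, medium, source, r, phase)
    return crossing_radius(r, profile + protocol.ambient_temperature_c, threshold_c)


def parameter_sweep(
    base_protocol: LaserProtocol,
    medium: Medium,
    source: SourceModel,
    powers_mw: Sequence[float],
    frequencies_hz: Sequence[float],
    duty_cycles: Sequence[float],
    *,
    threshold_c: float = 35.0,
):
    """Peak temperature rise and 35-degree isotherm radius over a protocol grid.

    One row per (power, frequency, duty-cycle) combination, in deterministic
    nested order.  Duty cycle 1 rows are evaluated as CW.
    """
    import pandas as pd

    powers = list(powers_mw)
    freqs = list(frequencies_hz)
    duties = list(duty_cycles)
    if not powers or not freqs or not duties:
        raise ValueError("sweep grids must be non-empty")
    if any(d <= 0 or d > 1 for d in duties):
        raise ValueError("duty cycles must lie in (0, 1]")
    rows = []
    for p in powers:
        for f in freqs:
            for d in duties:
                if d >= 1.0 - 1e-12:
                    proto = replace(
                        base_protocol, mode="cw", incident_power_mw=p,
                        repetition_frequency_hz=None, pulse_length_ms=None,
                    )
                    pulse_ms = None
                else:
                    pulse_ms = d / f * 1e3
                    proto = replace(
                        base_protocol, mode="pulsed", incident_power_mw=p,
                        repetition_frequency_hz=f, pulse_length_ms=pulse_ms,
                    )
                peak = peak_delta_t(proto, medium, source)
                r35 = lateral_isotherm_radius(proto, medium, source, threshold_c)
                rows.append(
                    {
                        "power_mw": p,
                        "frequency_hz": f,
                        "duty_cycle": d,
                        "pulse_length_ms": pulse_ms,
                        "peak_dT_C": peak,
                        f"r{threshold_c:g}_lateral_um": r35,
                    }
                )
    return pd.DataFrame(rows)
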