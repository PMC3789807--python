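"""Ground-truth-bundled synthetic fluorescence scenes for pipeline testing.

Emulates the raw inputs of GFP-lawn thermometry without a microscope:

* a textured fluorescent lawn (GFP-expressing bacteria spread on an agarose
  pad), modelled as a log-normal multiplicative field with Gaussian spatial
  correlation;
* calibration stacks of that lawn at stepped temperatures with cumulative
  photobleaching;
* laser-off / laser-on measurement pairs under a CW or pulsed focal heat
  source, optionally phase-gated, with shot and read noise.

Every generator is a pure function of its parameters and an explicit seed,
and every scene carries the exact temperature field, calibration curve and
noise parameters that generated it (`SceneTruth`), so expected noiseless
images can be recomputed bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .heat_model import (
    LaserProtocol,
    Medium,
    SourceModel,
    TemperatureField,
    gated_time_average,
    pulse_train_field,
)
from .thermometry import CalibrationCurve, GateWindow

__all__ = [
    "NoiseModel",
    "SceneTruth",
    "make_lawn_base",
    "render_fluorescence",
    "make_calibration_series",
    "make_measurement_pair",
    "write_standard_fixtures",
]


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise plus Gaussian read noise.

    ``photon_scale`` is the counts-per-photon gain: recorded counts are
    ``photon_scale * Poisson(I / photon_scale)``, so the shot-noise variance is
    ``photon_scale * mean``.  ``math.inf`` (or `None` via :meth:`noiseless`)
    disables shot noise.  At the default gain of 1, counts are pure Poisson
    (variance equals the mean).
    """

    photon_scale: float = 1.0
    read_noise_sd: float = 0.0
    dark_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.photon_scale <= 0:
            raise ValueError("photon scale must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read-noise sd must be non-negative")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(photon_scale=math.inf, read_noise_sd=0.0, dark_offset=0.0)

    @property
    def is_noiseless(self) -> bool:
        return math.isinf(self.photon_scale) and self.read_noise_sd == 0.0

    def apply(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(expected, dtype=float)
        if not math.isinf(self.photon_scale):
            out = self.photon_scale * rng.poisson(out / self.photon_scale).astype(float)
        if self.read_noise_sd > 0:
            out = out + rng.normal(0.0, self.read_noise_sd, size=out.shape)
        return out + self.dark_offset


@dataclass
class SceneTruth:
    """A synthetic scene bundled with everything that generated it."""

    images: dict[str, np.ndarray]
    noiseless_images: dict[str, np.ndarray]
    base: np.ndarray
    delta_t_fields: dict[str, np.ndarray | float]
    curve: CalibrationCurve
    noise: NoiseModel
    seed: int
    ambient_c: float
    exposure_s: float = 1.0
    bleach_rate: float = 0.0
    temperatures_c: list[float] | None = None
    pixel_size_um: float | None = None
    metadata: dict = dc_field(default_factory=dict)

    def expected_image(self, key: str) -> np.ndarray:
        """Recompute the expected noiseless image for ``key`` from stored truth."""
        bleach = 1.0
        if self.temperatures_c is not None and key.startswith("frame_"):
            i = int(key.split("_")[1])
            bleach = math.exp(-self.bleach_rate * i)
        return render_fluorescence(
            self.base * bleach,
            self.delta_t_fields[key],
            self.curve,
            ambient_c=self.ambient_c,
            exposure_s=self.exposure_s,
            noise=None,
        )


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def make_lawn_base(
    shape: tuple[int, int] = (256, 256),
    mean_intensity: float = 5000.0,
    texture_amplitude: float = 0.2,
    correlation_length_px: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Textured fluorescent lawn: log-normal field with Gaussian correlation.

    The texture is multiplicative and strictly positive, with relative
    standard deviation ``texture_amplitude`` and expected value exactly
    ``mean_intensity``.  The same seed always yields the same image.
    """
    if min(shape) < 64:
        raise ValueError("lawn images must be at least 64x64 pixels")
    if not 0.0 <= texture_amplitude < 1.0:
        raise ValueError("texture amplitude must lie in [0, 1)")
    if mean_intensity <= 0:
        raise ValueError("mean intensity must be positive")
    if texture_amplitude == 0.0:
        return np.full(shape, float(mean_intensity))
    rng = _rng(seed)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=correlation_length_px, mode="wrap")
    smooth = smooth / smooth.std()
    sigma_log = math.sqrt(math.log(1.0 + texture_amplitude**2))
    return mean_intensity * np.exp(sigma_log * smooth - 0.5 * sigma_log**2)


def render_fluorescence(
    base: np.ndarray,
    delta_t,
    curve: CalibrationCurve,
    *,
    ambient_c: float = 23.0,
    exposure_s: float = 1.0,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Forward imaging model: temperature-scaled base intensity plus noise.

    ``base`` is the scene as imaged at ambient temperature with a 1-second
    exposure; the expected image under a temperature-rise field dT is

        I = base * relI(ambient + dT) / relI(ambient) * exposure_s

    with relI the calibration curve's linear law — exactly what the
    intensity-ratio thermometry inverts, so the noiseless render/measure
    round trip is exact.  ``delta_t`` may be a scalar, an array matching
    ``base``, or a `TemperatureField` single z-slice; it is a signed offset
    (calibration frames below ambient are legitimate renders).
    """
    base = np.asarray(base, dtype=float)
    if isinstance(delta_t, TemperatureField):
        if delta_t.values.shape[0] != 1:
            raise ValueError("render expects a single-plane temperature field")
        dt = delta_t.values[0]
    else:
        dt = np.asarray(delta_t, dtype=float)
    if exposure_s <= 0:
        raise ValueError("exposure must be positive")
    rel = curve.relative_intensity(ambient_c + dt) / curve.relative_intensity(ambient_c)
    expected = base * rel * exposure_s
    if np.any(expected < 0):
        raise ValueError(
            "temperature excursion drives the linear law negative; "
            "outside the model's validity range"
        )
    if noise is None or noise.is_noiseless:
        return (expected + (0.0 if noise is None else noise.dark_offset)).astype(float)
    return noise.apply(expected, _rng(seed))


def make_calibration_series(
    temperatures_c,
    curve: CalibrationCurve | None = None,
    bleach_rate: float = 0.0,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    *,
    shape: tuple[int, int] = (64, 64),
    mean_intensity: float = 5000.0,
    texture_amplitude: float = 0.2,
    exposure_s: float = 1.0,
) -> SceneTruth:
    """Calibration stack: the same lawn imaged at stepped temperatures.

    Frame ``i`` is rendered at ``temperatures_c[i]`` with cumulative
    photobleaching factor ``exp(-bleach_rate * i)``.  Temperatures must lie in
    the curve's validity range (20-60 C by default).
    """
    temps = [float(t) for t in np.atleast_1d(np.asarray(temperatures_c, dtype=float))]
    if len(temps) == 0:
        raise ValueError("temperature list must be non-empty")
    curve = curve or CalibrationCurve.gfp_default(reference_temperature_c=temps[0])
    lo, hi = curve.valid_range_c
    if min(temps) < lo - 1e-9 or max(temps) > hi + 1e-9:
        raise ValueError(f"calibration temperatures must lie within {lo}-{hi} C")
    noise = noise or NoiseModel.noiseless()
    rng = _rng(seed)
    seed_int = seed if isinstance(seed, int) else -1
    base = make_lawn_base(shape, mean_intensity, texture_amplitude, seed=rng)
    ambient = curve.reference_temperature_c
    images: dict[str, np.ndarray] = {}
    clean: dict[str, np.ndarray] = {}
    fields: dict[str, np.ndarray | float] = {}
    for i, t in enumerate(temps):
        key = f"frame_{i}"
        bleached = base * math.exp(-bleach_rate * i)
        dt = t - ambient
        clean[key] = render_fluorescence(
            bleached, dt, curve, ambient_c=ambient, exposure_s=exposure_s, noise=None
        )
        images[key] = render_fluorescence(
            bleached, dt, curve, ambient_c=ambient, exposure_s=exposure_s,
            noise=noise, seed=rng,
        )
        fields[key] = dt
    return SceneTruth(
        images=images,
        noiseless_images=clean,
        base=base,
        delta_t_fields=fields,
        curve=curve,
        noise=noise,
        seed=seed_int,
        ambient_c=ambient,
        exposure_s=exposure_s,
        bleach_rate=bleach_rate,
        temperatures_c=temps,
    )


def _pixel_grid(shape: tuple[int, int], pixel_size_um: float):
    ny, nx = shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_size_um
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel_size_um
    return x, y, np.zeros(1)


def make_measurement_pair(
    protocol: LaserProtocol,
    medium: Medium | None = None,
    source: SourceModel | None = None,
    curve: CalibrationCurve | None = None,
    noise: NoiseModel | None = None,
    *,
    gates: dict[str, GateWindow] | None = None,
    seed: int | np.random.Generator = 0,
    shape: tuple[int, int] = (500, 500),
    pixel_size_um: float = 0.1,
    mean_intensity: float = 5000.0,
    texture_amplitude: float = 0.2,
    exposure_s: float = 1.0,
) -> SceneTruth:
    """Laser-off / laser-on image pair(s) of a lawn under focal heating.

    The off image shows the lawn at ambient; each on image shows it under the
    protocol's temperature field — the steady state for CW, or the gate-window
    time-average for each supplied `GateWindow` (pulsed only).  Without gates a
    pulsed protocol is imaged at its cycle time-average (ungated continuous
    excitation).  The exact generating fields are stored in the truth.

    Default field of view is 50x50 um at 0.1 um/pixel (100x objective scale),
    so micron-scale isotherm radii span many pixels.
    """
    medium = medium or Medium.water()
    source = source or SourceModel()
    curve = curve or CalibrationCurve.gfp_default(protocol.ambient_temperature_c)
    noise = noise or NoiseModel.noiseless()
    if gates is not None and protocol.mode == "cw":
        raise ValueError("gate windows apply to pulsed protocols only")
    if gates is not None:
        for name, gate in gates.items():
            if not math.isclose(
                gate.cycle_period_ms, protocol.period_ms, rel_tol=1e-9
            ):
                raise ValueError(
                    f"gate {name!r} cycle period {gate.cycle_period_ms} ms "
                    f"differs from protocol period {protocol.period_ms} ms"
                )
    rng = _rng(seed)
    seed_int = seed if isinstance(seed, int) else -1
    base = make_lawn_base(shape, mean_intensity, texture_amplitude, seed=rng)
    grid = _pixel_grid(shape, pixel_size_um)
    ambient = protocol.ambient_temperature_c

    on_fields: dict[str, np.ndarray] = {}
    if protocol.mode == "cw" or protocol.duty_cycle >= 1.0 - 1e-9:
        on_fields["on"] = pulse_train_field(
            protocol, medium, source, grid, "steady_state"
        ).values[0]
    elif gates is None:
        on_fields["on"] = pulse_train_field(
            protocol, medium, source, grid, "time_average"
        ).values[0]
    else:
        for name, gate in gates.items():
            on_fields[name] = gated_time_average(
                protocol, medium, source, grid, gate.start_ms, gate.end_ms
            ).values[0]

    images: dict[str, np.ndarray] = {}
    clean: dict[str, np.ndarray] = {}
    fields: dict[str, np.ndarray | float] = {"off": 0.0}
    clean["off"] = render_fluorescence(
        base, 0.0, curve, ambient_c=ambient, exposure_s=exposure_s, noise=None
    )
    images["off"] = render_fluorescence(
        base, 0.0, curve, ambient_c=ambient, exposure_s=exposure_s,
        noise=noise, seed=rng,
    )
    for name, dt in on_fields.items():
        fields[name] = dt
        clean[name] = render_fluorescence(
            base, dt, curve, ambient_c=ambient, exposure_s=exposure_s, noise=None
        )
        images[name] = render_fluorescence(
            base, dt, curve, ambient_c=ambient, exposure_s=exposure_s,
            noise=noise, seed=rng,
        )
    return SceneTruth(
        images=images,
        noiseless_images=clean,
        base=base,
        delta_t_fields=fields,
        curve=curve,
        noise=noise,
        seed=seed_int,
        ambient_c=ambient,
        exposure_s=exposure_s,
        pixel_size_um=pixel_size_um,
        metadata={"protocol_mode": protocol.mode},
    )


# Interleaved temperature order used for calibration fixtures: decorrelates
# frame index from temperature so the bleaching rate stays identifiable.
CALIBRATION_TEMPERATURES_C = [20.0, 60.0, 30.0, 50.0, 25.0, 55.0, 35.0, 45.0, 40.0]


def write_standard_fixtures(
    outdir,
    seed: int = 0,
    *,
    shape: tuple[int, int] = (128, 128),
    pixel_size_um: float = 0.4,
    noise: NoiseModel | None = None,
):
    """Materialize the standard synthetic test set as TIFF + JSON sidecars.

    Writes a nine-temperature calibration stack, a CW off/on pair at 23 C
    ambient, and phase-gated pulsed pairs (1 kHz / 0.2 ms; gates 0.1-0.2 ms
    in-pulse and 0.8-0.9 ms inter-pulse) at 23 C and 18 C ambient.
    Returns a dict of written TIFF paths.
    """
    from pathlib import Path

    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    noise = noise or NoiseModel.noiseless()
    medium = Medium.water()
    source = SourceModel()
    written: dict[str, object] = {}

    temps = CALIBRATION_TEMPERATURES_C
    series = make_calibration_series(
        temps, bleach_rate=0.01, noise=noise, seed=seed, shape=shape
    )
    stack = np.stack([series.images[f"frame_{i}"] for i in range(len(temps))])
    written["calibration_stack"] = io.write_image(
        outdir / "calibration_stack.tif",
        stack,
        {
            "exposure_s": series.exposure_s,
            "ambient_C": series.ambient_c,
            "pixel_size_um": pixel_size_um,
            "temperatures_C": temps,
            "bleach_rate_per_frame": series.bleach_rate,
            "seed": seed,
        },
    )

    def _write_pair(name, protocol, gates=None):
        scene = make_measurement_pair(
            protocol, medium, source, noise=noise, gates=gates,
            seed=seed, shape=shape, pixel_size_um=pixel_size_um,
        )
        meta = {
            "exposure_s": scene.exposure_s,
            "ambient_C": scene.ambient_c,
            "pixel_size_um": pixel_size_um,
            "seed": seed,
            "mode": protocol.mode,
        }
        for key, img in scene.images.items():
            gate_meta = dict(meta)
            if gates and key in gates:
                gate_meta["gate_ms"] = [gates[key].start_ms, gates[key].end_ms]
            written[f"{name}_{key}"] = io.write_image(
                outdir / f"{name}_{key}.tif", img, gate_meta
            )
        return scene

    from .heat_model import normalize_to_peak

    cw = LaserProtocol(
        mode="cw", repetition_frequency_hz=None, pulse_length_ms=None,
    )
    cw = normalize_to_peak(cw, medium, source, 50.0)
    _write_pair("cw_pair", cw)

    pulsed = LaserProtocol(mode="pulsed", repetition_frequency_hz=1000.0,
                           pulse_length_ms=0.2)
    pulsed = normalize_to_peak(pulsed, medium, source, 50.0)
    gates = {
        "in_pulse": GateWindow(0.1, 0.2, 1.0),
        "inter_pulse": GateWindow(0.8, 0.9, 1.0),
    }
    _write_pair("pulsed_23C", pulsed, gates)
    _write_pair("pulsed_18C", pulsed.with_ambient(18.0), gates)
    return written
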