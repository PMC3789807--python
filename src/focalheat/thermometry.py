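"""GFP-fluorescence thermometry: intensity-ratio temperature imaging.

GFP fluorescence decreases approximately linearly with temperature (about
1%/degree C over 20-60 C), which turns any GFP-expressing scene — e.g. a lawn
of GFP-expressing bacteria — into a temperature sensor.  The workflow:

1. **Calibrate**: image the same field of view at stepped, thermocouple-read
   temperatures, correct for photobleaching, and fit a line to the normalized
   mean ROI intensity versus temperature.  The slope (fraction per degree,
   negative for GFP) and its validity range form the calibration curve.

2. **Measure**: acquire a laser-off and a laser-on image at equal exposure,
   divide them pixel-by-pixel, and invert the linear law to obtain a per-pixel
   temperature-rise map.

3. **Phase-gate** (pulsed protocols): excite fluorescence only during a stated
   sub-window of the pulse cycle so the camera reports the temperature during
   (or between) laser pulses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .heat_model import LaserProtocol, Medium, SourceModel

__all__ = [
    "CalibrationCurve",
    "GateWindow",
    "TemperatureMap",
    "fit_calibration",
    "bleach_correct",
    "ratio_to_temperature",
    "radial_profile",
    "phase_gated_profiles",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear fluorescence-vs-temperature law I(T) = I_ref*(1 + s*(T - T_ref)).

    ``slope`` is the fractional intensity change per degree C referenced to the
    intensity at ``reference_temperature`` (negative for GFP, about -0.01).
    """

    slope: float
    reference_temperature_c: float = 23.0
    reference_intensity: float = 1.0
    valid_range_c: tuple[float, float] = (20.0, 60.0)
    fit_quality: float = float("nan")  # R^2; NaN flags a degenerate fit

    def __post_init__(self) -> None:
        lo, hi = self.valid_range_c
        if not lo < hi:
            raise ValueError("validity range must satisfy lower < upper")
        if abs(self.slope) >= 0.1:
            raise ValueError(
                f"slope magnitude {abs(self.slope):.3f}/C outside sanity bound 0.1/C"
            )
        if self.reference_intensity <= 0:
            raise ValueError("reference intensity must be positive")
        for t in self.valid_range_c:
            if self.relative_intensity(t) <= 0:
                raise ValueError(
                    "linear law goes non-positive inside the validity range"
                )

    def relative_intensity(self, temperature_c) -> np.ndarray | float:
        """Intensity relative to the reference temperature."""
        return 1.0 + self.slope * (np.asarray(temperature_c, dtype=float)
                                   - self.reference_temperature_c)

    def predict(self, temperature_c):
        return self.reference_intensity * self.relative_intensity(temperature_c)

    @classmethod
    def gfp_default(cls, reference_temperature_c: float = 23.0) -> "CalibrationCurve":
        """The canonical GFP sensitivity: -1% per degree C over 20-60 C."""
        return cls(slope=-0.01, reference_temperature_c=reference_temperature_c)


@dataclass(frozen=True)
class GateWindow:
    """Excitation window within the laser pulse cycle (all times in ms)."""

    start_ms: float
    end_ms: float
    cycle_period_ms: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.start_ms < self.end_ms <= self.cycle_period_ms:
            raise ValueError(
                "gate must satisfy 0 <= start < end <= cycle period "
                f"(got {self.start_ms}..{self.end_ms} of {self.cycle_period_ms} ms)"
            )

    @property
    def length_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class TemperatureMap:
    """Per-pixel temperature rise above ambient, with a validity mask.

    Pixels whose laser-off intensity fell at or below the noise floor are
    masked (never silently zeroed); pixels whose absolute temperature falls
    outside the calibration validity range are flagged but not altered.
    """

    delta_t: np.ndarray
    mask: np.ndarray  # True where the pixel is valid
    ambient_c: float
    pixel_size_um: float = 1.0
    focus_center: tuple[int, int] | None = None
    out_of_range: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta_t = np.asarray(self.delta_t, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.delta_t.shape:
            raise ValueError("mask and map shapes differ")
        if not np.all(np.isfinite(self.delta_t[self.mask])):
            raise ValueError("temperature map non-finite on valid pixels")
        if self.out_of_range is None:
            lo, hi = 20.0, 60.0
            abs_t = self.delta_t + self.ambient_c
            self.out_of_range = self.mask & ((abs_t < lo) | (abs_t > hi))

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def absolute(self) -> np.ndarray:
        return self.delta_t + self.ambient_c


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def _roi_means(intensities) -> np.ndarray:
    out = []
    for item in intensities:
        arr = np.asarray(item, dtype=float)
        out.append(float(arr.mean()) if arr.ndim else float(arr))
    return np.asarray(out)


def fit_calibration(
    temperatures_c,
    intensities,
    *,
    bleach_corrected: bool = True,
    reference_temperature_c: float | None = None,
    valid_range_c: tuple[float, float] = (20.0, 60.0),
) -> CalibrationCurve:
    """Least-squares line through normalized ROI intensity versus temperature.

    ``intensities`` may be scalars (ROI means) or images (averaged here).
    Intensities are normalized to the first frame's ROI mean, making the
    fitted slope a unit-free fraction per degree C.  The slope is referenced
    to ``reference_temperature_c`` (default: the first temperature in the
    series, the frame used for normalization).

    Requires at least three distinct temperatures.  A constant-intensity
    series yields slope 0 with NaN fit quality (degenerate, flagged).
    """
    temps = np.asarray(temperatures_c, dtype=float)
    means = _roi_means(intensities)
    if temps.shape != means.shape:
        raise ValueError("temperature and intensity series lengths differ")
    if np.unique(temps).size < 3:
        raise ValueError("calibration requires >= 3 distinct temperatures")
    if temps.min() < valid_range_c[0] - 1e-9 or temps.max() > valid_range_c[1] + 1e-9:
        warnings.warn("calibration temperatures extend beyond the validity range")
    if np.any(means <= 0):
        raise ValueError("calibration intensities must be positive")
    if not bleach_corrected:
        warnings.warn(
            "fitting uncorrected intensities; photobleaching will bias the slope"
        )
    t_ref = float(temps[0]) if reference_temperature_c is None else float(
        reference_temperature_c
    )
    norm = means / means[0]
    if np.allclose(norm, norm[0], rtol=0, atol=1e-12):
        return CalibrationCurve(
            slope=0.0,
            reference_temperature_c=t_ref,
            reference_intensity=float(means[0]),
            valid_range_c=valid_range_c,
            fit_quality=float("nan"),
        )
    res = stats.linregress(temps, norm)
    pred_ref = res.intercept + res.slope * t_ref
    if pred_ref <= 0:
        raise ValueError("fitted line non-positive at the reference temperature")
    slope = res.slope / pred_ref
    return CalibrationCurve(
        slope=float(slope),
        reference_temperature_c=t_ref,
        reference_intensity=float(means[0] * pred_ref),
        valid_range_c=valid_range_c,
        fit_quality=float(res.rvalue**2),
    )


def _joint_decay_fit(means: np.ndarray, temps: np.ndarray, idx: np.ndarray) -> float:
    """Decay rate of I_i = a * (1 + b*(T_i - T_0)) * exp(-rate * i).

    Fitting the multiplicative model directly (rather than a log-linear
    approximation) keeps the linear temperature response from leaking into
    the decay estimate; identifiable when acquisition order is not perfectly
    collinear with temperature.
    """
    from scipy.optimize import curve_fit

    t0 = temps[0]

    def model(x, a, b, rate):
        t, i = x
        return a * (1.0 + b * (t - t0)) * np.exp(-rate * i)

    # log-linear starting point
    design = np.column_stack([np.ones(idx.size), temps, idx])
    coef, *_ = np.linalg.lstsq(design, np.log(means), rcond=None)
    p0 = (float(means[0]), float(coef[1]), -float(coef[2]))
    try:
        popt, _ = curve_fit(model, (temps, idx), means, p0=p0, maxfev=10000)
        return float(popt[2])
    except RuntimeError:  # pragma: no cover - fall back to log-linear estimate
        return -float(coef[2])


def bleach_correct(
    stack,
    model: str = "exponential",
    *,
    temperatures_c=None,
    reference_indices=None,
    frame_axis: int = 0,
):
    """Correct an ordered image stack for photobleaching.

    Fits an exponential decay ``I_i ~ exp(-rate * i)`` to the frame means and
    multiplies each frame by the inverse decay factor — a per-frame scalar, so
    within-frame intensity ratios are untouched.

    ``model="exponential"`` fits all frames; when the frames were acquired at
    different temperatures, pass ``temperatures_c`` so the (linear) temperature
    trend is regressed out jointly and not absorbed into the decay rate.
    ``model="reference_frames"`` fits the decay only on ``reference_indices``,
    frames acquired under identical conditions.

    Returns ``(corrected_stack, rate)``; a non-positive fitted rate issues a
    warning and applies the identity correction.
    """
    arr = np.asarray(stack, dtype=float)
    if frame_axis != 0:
        arr = np.moveaxis(arr, frame_axis, 0)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("bleach correction requires >= 2 frames")
    means = arr.reshape(n, -1).mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("frame means must be positive")
    idx = np.arange(n, dtype=float)
    log_m = np.log(means)

    if model == "exponential":
        if temperatures_c is not None:
            temps = np.asarray(temperatures_c, dtype=float)
            if temps.shape != (n,):
                raise ValueError("temperature covariate length mismatch")
            rate = _joint_decay_fit(means, temps, idx)
        else:
            design = np.column_stack([np.ones(n), idx])
            coef, *_ = np.linalg.lstsq(design, log_m, rcond=None)
            rate = -float(coef[-1])
    elif model == "reference_frames":
        if reference_indices is None or len(reference_indices) < 2:
            raise ValueError("reference_frames model needs >= 2 reference indices")
        ref = np.asarray(reference_indices, dtype=int)
        slope, _intercept, *_ = stats.linregress(idx[ref], log_m[ref])
        rate = -float(slope)
    else:
        raise ValueError(f"unknown bleaching model {model!r}")

    if rate <= 0:
        if rate < -1e-12:
            warnings.warn(
                f"fitted bleaching rate {rate:.3g} is non-positive; "
                "applying identity correction"
            )
        rate = 0.0
    factors = np.exp(rate * idx)
    corrected = arr * factors[(...,) + (None,) * (arr.ndim - 1)]
    if frame_axis != 0:
        corrected = np.moveaxis(corrected, 0, frame_axis)
    return corrected, rate


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------


def ratio_to_temperature(
    image_off,
    image_on,
    curve: CalibrationCurve,
    ambient_c: float,
    *,
    pixel_size_um: float = 1.0,
    exposure_off_s: float | None = None,
    exposure_on_s: float | None = None,
    read_noise_sd: float = 0.0,
    dark_offset: float = 0.0,
) -> TemperatureMap:
    """Convert an off/on image pair into a temperature-rise map.

    Per pixel, the intensity ratio R = I_on / I_off is inverted through the
    linear law: dT = (1 - R) * (1 + s*(ambient - T_ref)) / |s|, which is exact
    for any calibration reference temperature.  The two images must share
    shape and (when metadata is supplied) exposure time — mismatched exposures
    are an error, never a rescale.  Pixels whose off-image intensity is at or
    below the noise floor (3x the read-noise sd) are masked.  ``dark_offset``
    is subtracted from both images before ratioing (default 0: no dark
    subtraction).
    """
    off = np.asarray(image_off, dtype=float) - dark_offset
    on = np.asarray(image_on, dtype=float) - dark_offset
    if off.shape != on.shape:
        raise ValueError(f"image shapes differ: {off.shape} vs {on.shape}")
    if exposure_off_s is not None and exposure_on_s is not None:
        if not math.isclose(exposure_off_s, exposure_on_s, rel_tol=1e-6):
            raise ValueError(
                f"exposure mismatch: off {exposure_off_s} s vs on {exposure_on_s} s"
            )
    elif (exposure_off_s is None) != (exposure_on_s is None):
        raise ValueError("exposure metadata supplied for only one image")
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; cannot invert intensities")

    floor = max(3.0 * read_noise_sd, 0.0)
    mask = np.isfinite(off) & np.isfinite(on) & (off > floor)
    delta_t = np.zeros_like(off)
    ratio = np.divide(on, off, out=np.ones_like(off), where=mask)
    amb_factor = 1.0 + curve.slope * (ambient_c - curve.reference_temperature_c)
    if amb_factor <= 0:
        raise ValueError("ambient lies outside the linear law's positive domain")
    delta_t[mask] = (1.0 - ratio[mask]) * amb_factor / abs(curve.slope)
    delta_t[~mask] = np.nan
    lo, hi = curve.valid_range_c
    abs_t = delta_t + ambient_c
    out_of_range = mask & ((abs_t < lo) | (abs_t > hi))
    return TemperatureMap(
        delta_t=np.where(mask, delta_t, 0.0),
        mask=mask,
        ambient_c=ambient_c,
        pixel_size_um=pixel_size_um,
        out_of_range=out_of_range,
    )


def find_focus_center(tmap: TemperatureMap, median_size: int = 3) -> tuple[int, int]:
    """Peak of the median-filtered map — robust focus localization."""
    if tmap.n_valid == 0:
        raise ValueError("temperature map is fully masked")
    filled = np.where(tmap.mask, tmap.delta_t, -np.inf)
    smoothed = ndimage.median_filter(filled, size=median_size, mode="nearest")
    idx = np.unravel_index(int(np.argmax(smoothed)), smoothed.shape)
    return int(idx[0]), int(idx[1])


def radial_profile(
    tmap: TemperatureMap,
    center: str | tuple[int, int] = "auto",
    *,
    bin_width_px: float = 1.0,
    median_size: int = 3,
) -> pd.DataFrame:
    """Azimuthal mean of the temperature map over one-pixel-wide annuli.

    Returns a DataFrame with columns r_um, mean_dT_C, sd_dT_C, n_pixels.
    ``center="auto"`` uses the peak of the median-filtered map.  Bins are
    limited to radii whose annuli lie fully inside the image.
    """
    if tmap.n_valid == 0:
        raise ValueError("temperature map is fully masked")
    if center == "auto":
        cy, cx = find_focus_center(tmap, median_size=median_size)
    else:
        cy, cx = int(center[0]), int(center[1])
    ny, nx = tmap.delta_t.shape
    if not (0 <= cy < ny and 0 <= cx < nx):
        raise ValueError("profile center lies outside the image")
    tmap.focus_center = (cy, cx)
    yy, xx = np.indices((ny, nx))
    r_px = np.hypot(yy - cy, xx - cx)
    r_max = min(cy, cx, ny - 1 - cy, nx - 1 - cx)
    sel = tmap.mask & (r_px <= max(r_max, bin_width_px))
    bins = (r_px[sel] / bin_width_px).astype(int)
    vals = tmap.delta_t[sel]
    n = np.bincount(bins)
    s1 = np.bincount(bins, weights=vals)
    s2 = np.bincount(bins, weights=vals**2)
    keep = n > 0
    mean = s1[keep] / n[keep]
    var = np.maximum(s2[keep] / n[keep] - mean**2, 0.0)
    r_centers = (np.nonzero(keep)[0] + 0.5) * bin_width_px * tmap.pixel_size_um
    return pd.DataFrame(
        {
            "r_um": r_centers,
            "mean_dT_C": mean,
            "sd_dT_C": np.sqrt(var),
            "n_pixels": n[keep],
        }
    )


def phase_gated_profiles(
    protocol: LaserProtocol,
    medium: Medium,
    source: SourceModel,
    gates: dict[str, GateWindow],
    curve: CalibrationCurve,
    noise=None,
    *,
    seed: int = 0,
    shape: tuple[int, int] = (129, 129),
    pixel_size_um: float = 0.4,
    smooth: bool = False,
) -> dict[str, pd.DataFrame]:
    """Simulated phase-gated thermometry: one radial profile per gate.

    Renders an off/on gated image pair for each gate window (the measured
    intensity is the time-average of the linear-in-T fluorescence over the
    gate, accumulated across many cycles), runs the intensity-ratio
    thermometry, and returns the recovered radial profiles keyed like
    ``gates`` (conventionally ``in_pulse`` and ``inter_pulse``).
    """
    from . import synthetic_data

    if protocol.mode != "pulsed":
        raise ValueError("phase-gated acquisition requires a pulsed protocol")
    if not gates:
        raise ValueError("at least one gate window is required")
    scene = synthetic_data.make_measurement_pair(
        protocol, medium, source, curve, noise,
        gates=gates, seed=seed, shape=shape, pixel_size_um=pixel_size_um,
    )
    off = scene.images["off"]
    profiles: dict[str, pd.DataFrame] = {}
    for name in gates:
        tmap = ratio_to_temperature(
            off, scene.images[name], curve, protocol.ambient_temperature_c,
            pixel_size_um=pixel_size_um,
        )
        if smooth:
            tmap.delta_t = ndimage.median_filter(tmap.delta_t, size=3)
        profiles[name] = radial_profile(tmap, center=(shape[0] // 2, shape[1] // 2))
    return profiles
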