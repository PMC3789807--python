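# Methods

## Heat-transport model

### Governing physics

The medium is treated as infinite, homogeneous and purely conductive water:
thermal conductivity k = 0.6 W·m⁻¹·K⁻¹, volumetric heat capacity
ρc = 4.18×10⁶ J·m⁻³·K⁻¹ (diffusivity α = k/ρc ≈ 1.43×10⁻⁷ m²·s⁻¹), and an
absorption coefficient of 2.3×10³ m⁻¹ at 1480 nm. These are standard
literature values for water near room temperature and are configurable; no
perfusion (Pennes) term and no temperature dependence of the constants are
modelled. The heat equation is linear, so fields scale exactly with absorbed
power and superpose over the source history — both facts are exploited
throughout (power normalization is a single field evaluation plus a scalar)
and asserted by tests.

The building block is the instantaneous point-release Green's function

    ΔT(r, t) = E / (ρc · (4παt)^{3/2}) · exp(−r² / 4αt),

a spatial Gaussian of width √(4αt) that conserves the deposited energy E
exactly. Continuous heating is its time integral; for an isotropic Gaussian
source of radius w heated over source-ages [s₀, s₁] this has the closed form

    ΔT(r) = P/(4πk r) · [erf(r/√(w²+4αs₀)) − erf(r/√(w²+4αs₁))],

whose s₁ → ∞ limit is the steady state P·erf(r/w)/(4πkr): the
inverse-distance law outside the source, finite at the origin. The package
uses this exact solution rather than capping an idealized 1/r profile at the
source boundary — it agrees with 1/r outside the source while remaining
consistent (to <1%) with the pulse-train superposition in the duty-cycle→1
limit, which a hard cap is not. Point-geometry sources keep the cap
convention: the on-axis value is reported as the value at r = w₀.

### Source geometry

The default source is a Gaussian spheroid with lateral radius w₀ = 1 µm and
axial radius w_z = 2 µm, the scale of a high-NA (≈1.3) focus; the axial
elongation w_z ≥ w₀ is enforced. For the spheroid the time integral has no
closed form; substituting v = 1/√(w₀²+4αs) yields

    ΔT = P/(2αρcπ^{3/2}) ∫ exp(−ρ²v² − z²v²/(1+Δv²)) / √(1+Δv²) dv,
    Δ = w_z² − w₀²,

a Gaussian-like integrand evaluated with 8-point Gauss–Legendre quadrature on
geometrically spaced panels (verified against the isotropic closed form to
~10⁻¹⁰, and against a finite-difference solver to ~1%).

The default absorbed fraction is μ_a·w_z ≈ 0.0046 — first-order
Beer–Lambert absorption over the axial focal radius. In reality absorption is
distributed along the whole converging beam, so absolute focal powers (and
hence absolute isotherm radii at a given incident power) are
order-of-magnitude estimates only; every headline quantity is therefore
computed after normalizing the field to a stated peak temperature, which
cancels this constant exactly.

### Pulse trains and phases

A pulsed protocol (repetition frequency f, pulse length τ, duty cycle
d = fτ ≤ 1) is evaluated at a stated phase of the quasi-periodic steady
state: `in_pulse_peak` (end of a pulse, the hottest instant), `inter_pulse`
(end of the off interval, the coolest), `time_average` (exactly the
duty-scaled CW steady state, by linearity), or any numeric phase in
milliseconds. Recent pulses are summed explicitly; the summation is truncated
once adding one more pulse changes the focal in-pulse peak by less than 0.1%
relative, and the remaining history is closed in analytic form as a
duty-scaled continuous source of isotropic-equivalent radius
√((2w₀²+w_z²)/3) — at those ages the diffusion length dwarfs the source, so
the anisotropy error is negligible. Duty cycle 1 is detected and evaluated as
CW. Sessions shorter than the convergence horizon simply sum every pulse
(this is how single-pulse fields are produced and validated against direct
quadrature of the Green's function, to 0.5%).

An optional half-space mode subtracts a mirrored field about a stated z
plane, mimicking an ideal heat-sinking coverslip; it is off by default.

### Isotherms and derived reports

Isotherm radii (default threshold: 35 °C absolute, a common whole-body
heat-shock temperature) are found along the principal axes through the field
peak by monotone bracketing with linear sub-grid interpolation; a flat-topped
(capped) peak resolves to its plateau centroid. A threshold above the peak
returns zero radii — an empty isotherm, not an error. Heated volume uses the
ellipsoid model (4/3)π·r_lat²·r_ax. The selectivity experiment evaluates the
three modes (CW at 23 °C, pulsed at 23 °C, pulsed at 18 °C ambient) on an
x–z plane with spacing w₀/8; the robustness scan across focal radii
{0.5, 1, 2 µm} × timings {30 Hz/1 ms, 100 Hz/2.5 ms, 1 kHz/0.2 ms} uses
dense 1-D lateral axes (spacing w₀/16) because the CW-vs-pulsed radius margin
at the slowest timing and smallest focus is only a few percent and needs
sub-grid accuracy. Units at the API surface are µm, ms, mW and °C; the
kernels are SI.

## Thermometry

### Forward model and calibration

GFP fluorescence follows the linear law I(T) = I_ref·(1 + s·(T − T_ref)),
with s ≈ −0.01 /°C valid over 20–60 °C. The fractional slope depends on the
reference temperature chosen; the package pins it explicitly
(`reference_temperature_c`, defaulting to the first frame of a calibration
series, which is also the normalization frame). Calibration is an ordinary
least-squares line through ROI-mean intensity normalized to the first frame,
reported with R²; a constant series yields slope 0 with NaN fit quality
(degenerate, flagged), and |s| ≥ 0.1 /°C trips a sanity bound.

Photobleaching is corrected by per-frame scalar factors exp(+λ̂·i), leaving
within-frame ratios untouched. For a pure-decay stack λ̂ comes from a
log-linear fit of frame means. When frames were acquired at different
temperatures the temperature response would leak into a naive decay fit, so a
temperature covariate can be supplied and the full multiplicative model
a·(1+b·(T_i−T₀))·exp(−λi) is fitted instead; this is identifiable only when
acquisition order is not perfectly collinear with temperature, which is why
the synthetic calibration series defaults to an interleaved temperature
order. A non-positive fitted rate warns and applies the identity. Two-frame
off/on pairs at different temperatures are left uncorrected (the model is
unidentifiable there), which the analysis pipeline handles as identity.

### Inverse model

Laser-off/laser-on pairs must share shape and (when metadata is present)
exposure time; a mismatch is an error, never a rescale. Per pixel,

    ΔT = (1 − I_on/I_off) · (1 + s·(T_ambient − T_ref)) / |s|,

the exact inversion of the linear law for any reference temperature — with
zero noise the render→measure round trip is exact to machine precision.
Pixels whose off intensity falls at or below 3× the read-noise sd are masked,
never zeroed; pixels whose absolute temperature leaves the calibration range
are flagged but not altered. Radial profiles are azimuthal means over
one-pixel annuli (width configurable) limited to annuli fully inside the
image; auto-centering takes the peak of a 3×3 median-filtered map.

### Phase gating

Gated acquisition integrates fluorescence only during a sub-window of the
pulse cycle across many cycles. Because intensity is linear in temperature,
the time-mean of intensity over the gate equals the intensity at the
time-mean temperature — the arithmetic-mean convention is exact here, not a
first-order approximation. The gate integral is evaluated with Gauss–Legendre
nodes on each smooth segment of the cycle (the field has a kink at the pulse
edge, so gates spanning it are split there); residual quadrature error is
below 1%.

## Synthetic scenes

The lawn (GFP-expressing bacteria on an agarose pad) is a log-normal
multiplicative texture with Gaussian spatial correlation — the simplest
strictly positive textured model — with exact expected mean, relative sd
`texture_amplitude` (default 0.2) and correlation length 5 px. The default
field of view is 50×50 µm at 0.1 µm/px (100× objective scale) so
micron-scale isotherm radii span many pixels; tests use smaller frames.
Camera noise is Poisson shot noise with a counts-per-photon gain
(`photon_scale`, default 1: counts are pure Poisson, variance = mean) plus
Gaussian read noise and a dark offset; an infinite gain disables shot noise,
giving the exactly invertible noiseless limit. Every generator is a pure
function of (parameters, seed) with no global random state, and each scene
stores the base image, exact ΔT fields, curve, noise model and seed, so
expected noiseless images can be recomputed bit-exactly.

What the generator does *not* emulate: optical blur/defocus (no PSF),
worm anatomy (a single-neuron scene is just a bright-disk variant of the
lawn), camera nonlinearity, dust, drift, or stage vibration. Passing
round-trip tests therefore demonstrates correctness of the analysis given
the stated imaging model, not robustness to every artefact of real
micrographs.

## Pipeline

The selectivity experiment normalizes each mode to a 50 °C peak
(hypothetical single-cell heat-shock peak) with ambients 23/23/18 °C and
reports radii, volumes and CW-to-cooled ratios; given the unpublished beam
parameters, printed micron values from instrument measurements are treated as
ordering/ratio targets, not absolute ones. Protocol design searches a
(frequency, pulse length, ambient) grid, ranks feasible candidates by
off-target isotherm radius and breaks ties by smaller duty cycle then lower
frequency (favouring thermal confinement); an empty feasible set is an
explicit result, not an exception. Every command is deterministic given
(config, seed), embeds the package version and a config hash in its outputs,
and writes machine-readable JSON run logs (the log carries a timestamp; data
files do not, so identical configs give byte-identical tables).

## Problem sizes and known limitations

Defaults were chosen so the full test suite and the acceptance script run in
well under a minute each on one core: 200 calibration replicates at 64×64 px,
selectivity planes of ~260² samples, robustness scans on 1-D axes, and one
64³ finite-difference cross-check (the FD pulse train uses a 10 kHz/0.02 ms
scaled-down timing so the whole train's diffusion length fits the box; the
code path exercised is identical for the experimental timings). Known
limitations: no bioheat/perfusion term, constant medium properties, no
damage or gene-induction biology, single-ROI thermometry (no segmentation),
and absolute absorbed power known only to order of magnitude (see Source
geometry above).
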