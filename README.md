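# focalheat

Heat-transport simulation and GFP-fluorescence thermometry for single-cell
laser heat shock.

A focused infrared laser (1480 nm, strongly absorbed by water) can heat a
single cell inside a living animal enough to trigger a heat-shock promoter —
but only if the hot region stays cell-sized. `focalheat` provides the
computational substrate for designing and measuring such experiments:

* **Heat transport** (`focalheat.heat_model`): temperature fields of
  continuous-wave (CW) and pulsed focal heating in an aqueous medium, built
  from the heat-equation Green's function
  `ΔT(r,t) = E/(ρc·(4παt)^{3/2})·exp(−r²/4αt)` and its superposition over the
  pulse history. CW heating settles into the inverse-distance steady state
  `ΔT(r) = P/(4πkr)`; brief pulses instead produce sharply peaked Gaussian
  transients that diffuse away between pulses, so a pulsed beam at matched
  peak temperature heats a much smaller region.
* **Thermometry** (`focalheat.thermometry`): GFP fluorescence falls roughly
  linearly with temperature (≈1 %/°C over 20–60 °C), so a GFP-expressing
  bacterial lawn is a temperature camera. The module fits the calibration
  line, corrects photobleaching, converts laser-off/laser-on image ratios to
  per-pixel temperature maps (`ΔT = (1 − I_on/I_off)/|s|`), computes radial
  profiles and isotherm radii, and models phase-gated excitation that reads
  the temperature *during* or *between* pulses.
* **Synthetic scenes** (`focalheat.synthetic_data`): seeded generators for
  calibration stacks, off/on pairs and gated acquisitions with shot/read
  noise, each bundled with the exact ground truth that produced it.
* **Pipeline + CLI** (`focalheat.pipeline`, `focalheat` command): the
  CW vs pulsed vs pulsed+cooled selectivity comparison, a protocol-design
  search, and an end-to-end analysis of measured TIFF pairs.

Intended users: experimentalists designing pulsed-laser heat-shock protocols
and anyone needing a tested reference implementation of intensity-ratio
fluorescence thermometry.

## Worked example

```python
import numpy as np
from focalheat import run_selectivity_experiment
from focalheat.synthetic_data import (
    CALIBRATION_TEMPERATURES_C, NoiseModel, make_calibration_series)
from focalheat.thermometry import (
    CalibrationCurve, bleach_correct, fit_calibration)

# 1. Spatial selectivity: CW vs pulsed (1 kHz / 0.2 ms) vs pulsed + cooling,
#    every mode normalized to a 50 C peak, isotherm threshold 35 C.
report = run_selectivity_experiment()
print(report.table[["mode", "ambient_C", "peak_T_C",
                    "lateral_radius_um", "axial_radius_um"]]
      .round(2).to_string(index=False))

# 2. Calibration round trip: synthetic GFP lawn stack at nine temperatures
#    (20-60 C, shot noise, 1%/frame bleaching), then the fitting pipeline.
temps = CALIBRATION_TEMPERATURES_C
curve = CalibrationCurve.gfp_default(reference_temperature_c=temps[0])
scene = make_calibration_series(temps, curve, bleach_rate=0.01,
                                noise=NoiseModel(), seed=0)
stack = np.stack([scene.images[f"frame_{i}"] for i in range(len(temps))])
corrected, rate = bleach_correct(stack, temperatures_c=temps)
fit = fit_calibration(temps, list(corrected), reference_temperature_c=temps[0])
print(f"fitted slope = {fit.slope * 100:.3f} %/C "
      f"(bleach rate {rate:.4f}/frame, R^2 = {fit.fit_quality:.5f})")
```

Output:

```
         mode  ambient_C  peak_T_C  lateral_radius_um  axial_radius_um
           CW       23.0      50.0               2.38             3.10
       pulsed       23.0      50.0               2.05             2.77
pulsed_cooled       18.0      50.0               1.71             2.39
fitted slope = -1.001 %/C (bleach rate 0.0101/frame, R^2 = 1.00000)
```

The table shows the defining ordering: at the same 50 °C peak, the region
heated above 35 °C shrinks from CW to pulsed illumination and shrinks further
when the ambient baseline is cooled from 23 °C to 18 °C (a higher threshold
temperature rise is then needed to cross 35 °C). Absolute radii scale with
the assumed focal-spot size (here w0 = 1 µm), so the ordering and ratios —
not the absolute microns — are the physically meaningful output. The
calibration fit recovers the generating −1 %/°C GFP sensitivity and the
1 %/frame bleaching rate from noisy data.

The same computations are available from a shell:

```bash
focalheat selectivity --outdir out/
focalheat synth --outdir fixtures/ --seed 1
focalheat calibrate --stack fixtures/calibration_stack.tif --outdir out/
focalheat measure --off fixtures/cw_pair_off.tif --on fixtures/cw_pair_on.tif \
    --calibration out/calibration.json --outdir out/
```

## Documentation

`docs/methods.md` describes the heat-transport model and its assumptions,
the thermometry forward/inverse model, the synthetic-data generator, and the
numerical choices (pulse-history truncation, quadrature, tie-breaking) in
detail.
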