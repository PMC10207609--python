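# dcequant

Quantification of tumor perfusion and vascular permeability from dynamic
contrast-enhanced (DCE) MRI, aimed at preclinical studies that track how
targeted therapies — antiangiogenics, immune checkpoint blockade — remodel
tumor vasculature. Conventional volumetry often misses these responses;
DCE-derived parameters capture them early. The package implements the full
single-slice analysis chain and a digital tumor phantom with known ground
truth to validate every stage.

## What it computes

- **T1 mapping** from a variable-TR saturation-recovery ladder,
  S(TR) = M0·(1 − e^(−TR/T1)), fitted per pixel, plus per-ROI
  **ΔT1 = T1_pre − T1_post**, a contrast-retention readout.
- **Signal → concentration** for spoiled gradient echo:
  S = M0 sin α (1 − E1)/(1 − cos α E1), E1 = e^(−TR·R1),
  R1 = 1/T10 + r1·C, inverted in closed form with per-pixel baseline
  calibration of M0.
- **Extended (three-parameter) Tofts model**
  Ct(t) = vp·Cp(t) + Ktrans·∫₀ᵗ Cp(τ)e^(−kep(t−τ))dτ, kep = Ktrans/ve,
  fitted pixel-wise by bounded least squares with an analytic Jacobian and
  a fixed multi-start scheme, driven by a population arterial input
  function with hematocrit correction Cp = Cb/(1 − Hct).
- **Semi-quantitative perfusion metrics**: area under the enhancement
  curve (AUC) and maximum upslope (slope_max), pixel-wise and per ROI.
- **Cohort statistics**: three viable-rim ROIs per animal, unweighted mean
  of ROI means per parameter, then a Shapiro–Wilk-gated (α = 0.05)
  two-tailed Welch t-test or Mann–Whitney U test between groups.
- **Digital phantom**: a rim/core/muscle tumor slice with known T1, M0,
  Ktrans, ve, vp per region, forward-simulated variable-TR ladders and
  dynamic FLASH series with Rician noise, and multi-animal treatment
  scenarios with known effect sizes.

Here Ktrans (min⁻¹) reads out capillary permeability, vp the plasma
volume fraction (vascularization), ve the interstitial volume fraction,
and AUC/slope_max tumor perfusion.

## Worked example

Simulate one noisy animal at SNR 20 and recover its rim parameters
(rim ground truth: Ktrans 0.25 min⁻¹, vp 0.04):

```python
import numpy as np
from dcequant import *

params = AcquisitionParams()          # 610 frames, ~1.967 s apart, bolus at 60 s
truth = make_truth(grid_shape=(48, 48), seed=7)
aif = evaluate_aif(AIFParams(), params.frame_times, params.hematocrit)

signal, _ = simulate_dce(truth, aif, params, snr=20.0, seed=7)

ctx = ConversionContext.from_params(truth.t1_map(), params)
conc, valid = signal_to_concentration(signal, ctx)

rois = place_rim_rois(truth)          # three non-overlapping rim ROIs
maps = fit_map(conc, aif, rois)
metrics = metric_maps(signal, rois, params)
rec = aggregate_animal({"Ktrans": maps["Ktrans"], "vp": maps["vp"],
                        "AUC": metrics["AUC"], "slope_max": metrics["slope_max"]},
                       rois, animal_id="m01", group="control")
for k, v in rec.values.items():
    print(f"{k:10s} {v:.4f}")
```

prints

```
Ktrans     0.2498
vp         0.0405
AUC        1039.8539
slope_max  0.1082
```

i.e. the per-animal Ktrans and vp land within ~1% of the programmed
truth; AUC is in seconds of relative enhancement and slope_max in s⁻¹.

The same chain is available from the shell: `dcequant phantom`,
`fit-t1`, `delta-t1`, `resample`, `to-conc`, `fit-pk`, `curve-metrics`,
`roi-stats`, `compare`, `report` (see `dcequant --help`), each writing
NIfTI/CSV outputs and an optional provenance log.

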