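# dixonperf

Free-breathing quantitative myocardial perfusion MRI analysis:
multi-echo Dixon water–fat separation, fat-image-guided motion
correction, T2* correction of the arterial input function, and
pixel-wise myocardial blood-flow (MBF) mapping with the two-compartment
exchange model — plus a fully synthetic dynamic cardiac phantom with
ground truth for every stage.

## Who this is for

Researchers working on first-pass cardiac perfusion MRI who need an
open, testable implementation of a Dixon-based free-breathing pipeline:
the respiratory motion of a free-breathing acquisition normally defeats
intensity-based registration because the contrast bolus changes the
image content frame to frame. The Dixon **fat** images are immune to
gadolinium, so they anchor the rigid motion estimate; the residual
non-rigid motion is then removed against a PCA synthetic reference that
shares each frame's contrast state.

## The pipeline

1. **Dixon separation** — per-pixel complex least squares of
   `s_n = (W + F·e^{i2πΔf·TE_n}) e^{i2πψ·TE_n}` over three echoes
   (TE 1.0/1.9/2.8 ms), optional variable-projection field-map
   estimation.
2. **Rigid stage** — each fat frame registered to the evolving mean fat
   frame (MSE, Nelder–Mead, 3-level pyramid, three passes) inside an
   automatically detected box around the left ventricle; the composed
   transforms are applied to the diagnostic water frames with a single
   resampling.
3. **Non-rigid stage** — each rigid-corrected water frame registered to
   its rank-3 temporal-PCA reconstruction with a cubic B-spline
   free-form deformation under the residual-complexity cost
   `Σ log(q²/α + 1)` (orthonormal-DCT coefficients `q`), which tolerates
   the smooth intensity mismatch between a frame and its low-rank
   reference.
4. **T2\* correction** — per-frame log-linear fit of the three-echo LV
   blood-pool signal to `S(TE) = M0·e^{−TE/T2*}`; `M0(t)` is the
   restored AIF.
5. **Quantification** — dual-bolus AIF (diluted pre-bolus rescaled and
   aligned to the main bolus) and pixel-wise fits of the 2CXM

       vp dCp/dt = Fp (C_aif/(1−Hct) − Cp) + PS (Ce − Cp)
       ve dCe/dt = PS (Cp − Ce),      Ct = vp Cp + ve Ce

   by bounded multi-start non-linear least squares or an
   empirical-Bayes MCMC hierarchy; MBF is `Fb = Fp/(1−Hct)`.
6. **Evaluation** — temporal smoothness of myocardial time–intensity
   curves, MBF-map SD, tMIP sharpness, trajectory RMS error against
   phantom ground truth, Mann–Whitney group comparison.

## Worked example

Fit one noisy tissue curve (SNR 40, true Fb = 1.0 mL/min/g):

```python
import numpy as np
import dixonperf as dp
from dixonperf.kinetics import (ConcentrationCurve, KineticParams,
                                TwoCompartmentExchangeModel, twocxm_forward)
from dixonperf.phantom import AifParams, gamma_variate_aif

t = np.arange(0, 45.0)
aif = ConcentrationCurve(t, gamma_variate_aif(AifParams(delay=3.0, amplitude=3.0), t))
truth = KineticParams.from_fb(1.0, 0.06, 0.2, 0.5)
ct = twocxm_forward(truth, aif)
rng = np.random.default_rng(0)
y = ct.value + rng.normal(0, ct.value.max() / 40, t.size)

res = TwoCompartmentExchangeModel(y, aif).fit()
print(res.summary())
```

```
Two-Compartment Exchange Model Results
======================================================
Method:        nlls   converged: True
N frames:      45
Residual norm: 0.02374
Hct:           0.42
------------------------------------------------------
param     estimate     std err   unit
Fp           0.576     0.02322   mL/min/g
vp         0.05628    0.006555   -
ve          0.2091    0.007447   -
PS           0.513     0.02855   mL/min/g
------------------------------------------------------
MBF Fb = Fp/(1-Hct) = 0.9931 mL/min/g
```

The estimated plasma flow Fp converts to a blood flow of
0.99 mL/min/g — within 1% of the true value; the standard errors come
from the Gauss–Newton approximation at the optimum. `fit_bayes()`
returns posterior summaries with credible intervals instead.

The whole pipeline runs on a synthetic phantom from the command line:

```bash
dixonperf run --out demo --seed 1
cat demo/metrics.json
```

which simulates a breathing, noisy acquisition, separates water/fat,
motion-corrects, T2*-corrects the AIF, fits the MBF map and writes the
evaluation metrics (temporal smoothness, MBF uniformity, trajectory RMS
error, tMIP sharpness). Individual stages are available as
`dixonperf simulate | separate | moco | t2star | quantify | evaluate`.

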