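# Methods

`dixonperf` implements a free-breathing quantitative myocardial perfusion
pipeline built around three ideas: (i) multi-echo Dixon water–fat
separation yields a fat image series that is untouched by the contrast
bolus and can drive simple intensity-based rigid registration; (ii) the
residual non-rigid motion in the rigid-corrected water series is small
enough to be invisible to the leading temporal principal components, so a
rank-3 reconstruction provides a motionless, contrast-matched reference
for non-rigid refinement; (iii) the same three echoes support a per-frame
mono-exponential T2* fit that restores the attenuated peak of the
arterial input function (AIF). Blood flow is quantified pixel-wise with
the two-compartment exchange model (2CXM).

This note documents the models, the defaults and their rationale, the
synthetic phantom that serves as ground truth, and the numerical choices.


## Signal model and phantom

The phantom emulates a saturation-recovery spoiled gradient-echo
acquisition with three echoes per excitation (TE 1.0/1.9/2.8 ms, flip
angle 14°, saturation delay TD 75 ms, 2.5 mm pixels, one 2D frame per
second). Per pixel and echo `n`:

    S_n = [ W e^(-TE_n R2*_w) + F e^(-TE_n R2*_f) e^(i 2π Δf_fat TE_n) ] e^(i 2π ψ TE_n)
    W   = PD_w sin(α) (1 − e^(−TD·R1_w)),  R1_w = 1/T1_0 + r1 C,  R2*_w = 1/T2*_0 + r2* C
    F   = PD_f sin(α) (1 − e^(−TD/T1_f))

with a single-peak fat model at −434 Hz (−3.4 ppm at 3 T) and relaxivities
r1 = 4.5, r2* = 6.0 L mmol⁻¹ s⁻¹ (typical gadolinium values at 3 T).
Gadolinium enhances the water relaxation rates only; the fat
magnetisation is unaffected — the property the whole motion-correction
scheme rests on. The saturation-recovery factor ignores readout-train
effects; that is adequate for exercising the pipeline mathematics and is
a phantom-only simplification.

Geometry is a short-axis slice: LV blood pool (radius 10 px at 128²),
myocardial annulus (outer radius 16 px, six angular sectors with
per-sector kinetic parameters), an RV pool abutting the septum, discrete
epicardial fat arcs of varying thickness plus a pericardial fat pad
(epicardial fat is patchy in vivo; the angular asymmetry is also what
makes rotation observable to the registration), a chest-wall fat band,
and a body ellipse. Baselines: T1 1900/1500/380/1000 ms and T2* 30/30/40/25 ms
for blood/myocardium/fat/body.

Contrast timeline: a gamma-variate bolus, peak-normalised,

    C(t) = A (τ/(s·w))^s e^(s − τ/w),  τ = t − delay,

with shape s = 3 and washout w = 1.5 s, i.e. a 4.5 s time-to-peak — a
realistic first-pass LV upstroke. The pre-bolus (10% dilution) arrives at
5 s and the main bolus (A = 3 mM, a rest-dose 0.05 mmol/kg scale) at
35 s of an 80 s acquisition; RV enhancement leads the LV by 3 s. Tissue
curves are exact 2CXM forward solutions driven by the total
(pre + main) AIF. Default sector kinetics are healthy rest myocardium:
Fb = 1.0 mL/min/g, vp = 0.06 (plasma fraction of a ~10% blood volume),
ve = 0.2, PS = 0.5 mL/min/g — PS is set so the first-pass gadolinium
extraction `1 − e^(−PS/Fp)` is ≈0.6, in line with Gd-DTPA literature.
These choices matter: a slower bolus or a higher extraction makes Fp
statistically unidentifiable at 1 Hz sampling (see "Identifiability").

Motion is a sinusoidal free-breathing model: head–foot-dominant
translation (5 px), in-plane 1.5 px, rotation ±3°, period 5 frames
(12 breaths/min at 1 frame/s), plus an optional smooth separable
displacement mode (default amplitude 1.5 px in the moving studies) that
vanishes at the image border. Noise is complex Gaussian per channel
(magnitude ≈ Rician), with SD expressed as a fraction of the baseline
myocardial signal.

What the phantom does **not** emulate: k-space sampling (SENSE, partial
Fourier), coil sensitivities, through-plane motion, multi-peak fat,
B0/B1 inhomogeneity beyond a constant ψ, heart-rate variability, and
arrhythmia-driven mistriggering. Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline mathematics under
controlled conditions, not clinical performance.


## Dixon separation

Given ψ, the two-species chemical-shift model is linear in (W, F) and is
solved per pixel by complex least squares over the echoes. ψ can be
fixed (scanner-provided), zero, or estimated per frame by variable
projection: a 1 Hz grid search over ±1/(2ΔTE) of the projection residual,
followed by snapping each pixel to the alias (spacing |Δf_fat|) closest
to the bright-pixel consensus — pure-fat pixels admit a swapped solution
— and magnitude-weighted Gaussian smoothing (σ = 3 px). The separation is
exactly invertible only when the water signal is echo-independent; with
T2* decay across echoes the least-squares solution absorbs a few percent
of model error, which is why the exact-inversion checks use a no-decay
phantom variant (r2* = 0, baseline T2* = ∞) while all dynamic-behaviour
checks use the full phantom.


## Two-stage motion correction

**Rigid, fat-guided.** A box around the left ventricle is found
automatically as the bounding box (margin 4 px) of the connected
component of maximal temporal signal variance — a deliberate stand-in
for a learned detector, adequate because first-pass enhancement
dominates the variance map. The threshold is taken relative to a robust
(90th-percentile) variance reference, not the single maximal pixel,
which motion flicker inflates. Each fat frame is registered to the mean
fat frame by Nelder–Mead over (tx, ty, θ) on a 3-level pyramid with an
MSE cost over the box; three passes are run with the mean recomputed
from corrected frames between passes (the first pass uses the mean of
the originals). Composed transforms are re-expressed about the image
centre and applied to the water frames with one resampling (no
iterative blur). The optimiser pivots rotations on the ROI centre for
conditioning only. Bounds: |t| ≤ N/4, |θ| ≤ 15°.

**Non-rigid, PCA-referenced.** The rigid-corrected water crop is
approximated by its leading three temporal principal components (the LV,
RV and myocardial enhancement modes); each frame is then registered to
its rank-3 reconstruction with a cubic B-spline free-form deformation
(knot spacing 8 px) minimising the residual-complexity cost

    RC(r) = Σ_i log(q_i²/α + 1),   q = orthonormal 2D DCT of the residual,

with α = 0.05 on images normalised to [0, 1] by the reference's 99th
percentile (the α default presumes normalised intensities), plus a
bending-energy regulariser (weight 0.01) on the control lattice.
Optimisation is L-BFGS with an analytic gradient over a 2-level pyramid;
the image-gradient term samples the precomputed moving-image gradient at
the warped coordinates (the exact chain rule), which is markedly more
accurate than differentiating the warped result. RC saturates on large
coefficients by design — that is what buys robustness to the smooth
contrast difference between a frame and its low-rank reference, at the
price of some geometric sharpness relative to MSE on matched pairs.

PCA is computed on the raw (un-normalised) ROI intensities; deformations
are estimated and applied on the ROI crop and pasted into the
rigid-corrected frame.


## T2* correction of the AIF

Per frame, the mean LV blood-pool magnitudes of the three echoes are fit
log-linearly to `S(TE) = M0 e^(−TE/T2*)`; `M0(t)` is the corrected AIF.
The log-linear fit is closed-form and deterministic; its noise bias is
acceptable at blood-pool SNR. T2* is clipped to (0.1, 1000] ms;
non-decaying frames are flagged and interpolated from neighbours. The
reported gain is the percentage increase of the peak-to-post-peak-baseline
ratio, with the baseline window running from 1.5× the uncorrected
time-to-peak to the end of the segment (the window definition is a
package choice; only orderings and signs are claimed, not any particular
percentage).


## Perfusion quantification

Signals convert to concentration linearly, `C = k (S − S̄0)` with the
baseline taken pre-contrast and k = 1 (relative units): Fb is invariant
to a common scale on AIF and tissue, which a test asserts. The measured
LV curve is split at the minimum between its two largest peaks; the
pre-bolus segment, scaled by 1/dilution and aligned to the main-bolus
arrival (10%-of-peak threshold crossing, nearest frame), becomes the AIF
of the main-bolus window. The fit window is extended by a few quiet
frames before the arrival so per-pixel baselines are estimated off the
upstroke.

The 2CXM

    vp dCp/dt = Fp (C_aif/(1−Hct) − Cp) + PS (Ce − Cp)
    ve dCe/dt = PS (Cp − Ce),        C_t = vp Cp + ve Ce,   Fb = Fp/(1−Hct)

uses the standard volume-weighted observation equation (the ODE pair
alone does not fix one) and Hct = 0.42. Two forward solvers exist: a
stiff ODE integration (Radau/LSODA, rtol 1e-9) and an exact
bi-exponential convolution — eigen-decomposition of the 2×2 system and a
closed-form exponential update per segment of the piecewise-linear
interpolated AIF (internally ×5 supersampled), run as a
constant-coefficient IIR filter. The two routes are independent and
cross-checked to 1e-4 over a parameter grid.

**NLLS.** Bounded trust-region least squares on (Fp, vp, ve, PS) with a
deterministic multi-start grid (default 5 starts), a fixed penalty row
enforcing vp + ve ≤ 1, and physiological bounds Fp ≤ 3 and vp ∈ [0.01, 0.3]
(myocardial plasma flow rarely exceeds 3 mL/min/g even under stress).
Pixel-wise mapping defaults to 2 starts and ×3 supersampling for speed.

**Empirical-Bayes hierarchy.** `fit_2cxm_bayes` implements a two-level
scheme: every pixel is first fitted by NLLS; the ensemble of estimates
sets a shared log-normal hyperprior on Fp and PS (median = ensemble
median, log-SD = MAD clipped to [0.1, 1]); each pixel is then sampled
with emcee under that shared prior (walkers initialised in a ball around
the pixel's NLLS estimate, or from the prior when the likelihood is
uninformative). This is an empirical-Bayes approximation to a full joint
hierarchy — the population level is estimated once rather than sampled —
chosen because it delivers the shrinkage that makes low-SNR pixel maps
usable at a small fraction of the cost of joint sampling. Convergence is
reported per pixel as split-chain R-hat (< 1.05 ⇒ "converged"); fits are
bit-reproducible for a fixed seed and chain configuration. Default
priors elsewhere: log-normal (median 1, log-SD 1) on Fp and PS, Beta on
vp and ve with vp + ve ≤ 1 enforced, Jeffreys-type 1/σ on the noise SD.

**Identifiability.** At 1 Hz sampling with a realistic bolus, Fp is
near the edge of identifiability: the Cramér–Rao bound for the default
conditions (SNR 20 on the tissue curve) gives an Fp CV of ≈10%, and it
degrades quickly if the bolus is slower or the extraction fraction
higher (the fast vascular mode then hides under the bolus width, and a
spike-plus-uptake model mimics the true curve far below the noise
level). vp is the least identifiable parameter (CV ≈ 100% at SNR 20);
vp/ve/PS recovery is only claimed within broad tolerances. The
physiological fit bounds cap, but do not remove, a degenerate
high-flow/low-vp ridge.


## Evaluation metrics

* **Temporal smoothness** — series robustly scaled to [0, 1] by the
  1st/99th percentiles over the masked voxels; per pixel, the SD of the
  central second temporal difference (endpoints excluded); mean over
  pixels. Zero iff curves are affine in time; invariant to offset and
  global scale. Absolute values depend on the normalisation choice, so
  only orderings between correction states are claimed.
* **MBF uniformity** — SD of Fb over the myocardial mask, flagged pixels
  excluded; in subjects (and phantoms) without perfusion defects lower
  is better.
* **tMIP sharpness** — Tenengrad (mean squared Sobel gradient) of the
  temporal maximum intensity projection, a proxy for the visual
  sharpness gain of aligned series.
* **Trajectory error** — RMS of the de-meaned difference between the
  estimated and true rigid parameters (registration recovers motion
  only up to the mean-frame gauge).
* **Group comparison** — two-sided Mann–Whitney U (exact for small
  tie-free samples), α = 0.05.


## Problem sizes of the bundled studies

The demo studies run at desk scale on one CPU: trajectory recovery on
the full 128² / 80-frame phantom; the ordering study on ten seeded 96² /
64-frame phantoms at 2% noise (the metric orderings are scale-free);
pixel fits in the ordering study use a once-eroded myocardial mask —
partial-volume pixels at the blood border mix LV signal under any
residual sub-pixel motion and rail their fits at the parameter bounds,
which would bury the uniformity metric under a state-independent
outlier floor. On these phantoms the map SD cleanly separates corrected
from uncorrected series, while the rigid-only and full corrections
differ in map SD by about a percent with no stable sign; the
superiority of the full two-stage correction over rigid-only shows in
the time-curve smoothness (and tMIP sharpness), not in the map SD —
both orderings are computed and reported by the bundled studies.
parameter recovery on 45-frame curves with 100 replicates at SNR 20 and
50 shared-truth pixels at SNR 10 with reduced chains (16 walkers × 400
steps). The pipeline itself has no scale assumptions.


## Known limitations

* 2D only; through-plane motion is neither simulated nor corrected.
* Single-peak fat; vendor mDixon output equivalence is not claimable.
* The rigid stage absorbs part of any smooth non-rigid truth motion into
  (tx, ty, θ); trajectory RMS against a rigid-only truth is therefore
  only meaningful on rigid-motion phantoms.
* Concentration linearity is assumed (as in the dual-bolus design);
  main-bolus T1 saturation is not corrected, and the T2* correction is
  demonstrated on the AIF, not propagated into quantification.
* The empirical-Bayes hierarchy understates population-level
  uncertainty relative to a full joint model.
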