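# Methods

`dcequant` quantifies tumor perfusion and vascular permeability from
single-slice dynamic contrast-enhanced (DCE) MRI, the way preclinical
studies of antiangiogenic and immune therapies do it: a variable-TR T1
measurement before and after contrast, a dynamic spoiled-gradient-echo
(FLASH) acquisition during bolus passage of a macromolecular
gadolinium agent, pharmacokinetic modeling with a population arterial
input function, and a two-group statistical comparison of per-animal
summary values. Because such animal datasets are rarely public, the
package ships a synthetic-data generator — a digital tumor phantom with
known ground truth — so every stage can be validated quantitatively.

## Signal models

**Saturation-recovery T1 mapping.** The variable-TR ladder is modeled as
S(TR) = M0·(1 − exp(−TR/T1)). The RARE echo train's effective-TE
weighting is absorbed into M0, the standard simplification for
variable-TR fitting. Per pixel, (M0, T1) are estimated by bounded
nonlinear least squares with T1 ∈ [50, 10000] ms; initialisation takes
M0 from the longest-TR signal and T1 from the TR at half-maximal
recovery (T1 ≈ TR½/ln 2). Pixels with no recovery curvature, solver
failure, or a bound-pinned T1 are flagged non-converged and excluded,
never filled. A constant-offset third parameter is deliberately not
fitted: with 8 ladder points it costs precision and the simulated data
contain no offset.

**ΔT1.** Contrast retention is summarised per ROI as
ΔT1 = mean(T1_pre) − mean(T1_post) over converged pixels, reported
unclamped so a contrast-free ROI can show its noise floor.

**SPGR conversion.** The dynamic signal follows
S = M0·sin α·(1 − E1)/(1 − cos α·E1) with E1 = exp(−TR·R1) and
R1(t) = 1/T10 + r1·C(t). Relaxivity is accepted in ms⁻¹mM⁻¹ or s⁻¹mM⁻¹
and stored in s⁻¹mM⁻¹ (default 4.5, i.e. 0.0045 ms⁻¹mM⁻¹). M0 is
calibrated per pixel from the pre-injection baseline mean (all frames
before the bolus minus a 2-frame guard), which makes the recovered
concentration invariant to receiver gain. Inversion is the closed-form
solution of the SPGR law on the physical branch E1 ∈ (0, 1) — not the
linearised low-concentration approximation, since macromolecular agents
at preclinical doses can leave the linear regime near vessels. Signals
at or above the saturation plateau M0·sin α are flagged invalid rather
than extrapolated; noise-driven negative concentrations are retained so
downstream least squares stays unbiased.

## Pharmacokinetic model

The extended (three-parameter) Tofts model
Ct(t) = vp·Cp(t) + Ktrans·∫₀ᵗ Cp(τ)·e^(−kep·(t−τ)) dτ, kep = Ktrans/ve,
is the bidirectional two-compartment model appropriate for an
albumin-binding agent whose extravasation marks pathologically leaky
endothelium. Ktrans and kep are reported in min⁻¹; all time axes are
seconds internally, converted in one place.

The convolution is evaluated by an interval-exact recursion for a
piecewise-linear Cp against the exponential kernel
(I_n = e^(−kep·Δt)·I_{n−1} + b_n with b_n in closed form). On uniform
grids the recursion is executed as an IIR filter in compiled code. This
avoids both the O(T²) cost and the grid bias of trapezoid quadrature;
against the closed-form solution for a mono-exponential input the error
is < 1e−4 mM at 2 s sampling across kep ∈ [0.1, 3] min⁻¹.

Fitting is bounded nonlinear least squares (trust-region reflective)
with an analytic Jacobian obtained by differentiating the same
recursion. Bounds: Ktrans ∈ [0, 5] min⁻¹, ve ∈ [1e−3, 1],
vp ∈ [0, 0.5]; ve + vp ≤ 1 is enforced by a quadratic penalty row.
Three fixed starting points (low/medium/high Ktrans) guard against
local minima deterministically; a start whose residual is at numerical
zero ends the search early. A "quick" mode, used only inside the
repeated-cohort pipeline, accepts the first start explaining ≥ 95% of
curve variance. Identifiability guards: a flat zero curve returns
(Ktrans = 0, vp = 0) with ve flagged unidentifiable; a post-bolus
observation window shorter than one reflux time constant 1/kep lowers
the convergence flag, since ve is then weakly constrained.

**Arterial input function.** No agent-specific measured population AIF
is bundled, so the package uses the minimal standard bolus shape: zero before arrival t0 (default 60 s, the bolus
starting one minute into the scan), a linear rise (5 s) to peak A
(default 3.0 mM in whole blood), then biexponential decay
(a1 = 0.7, m1 = 0.05 s⁻¹; a2 = 0.3, m2 = 0.002 s⁻¹). These defaults are
synthetic, fully config-driven, and converted from blood to plasma
exactly once via Cp = Cb/(1 − Hct) with Hct = 0.45. Fitting real data
would require the study-specific population AIF.

## Semi-quantitative metrics

Enhancement curves default to relative signal enhancement
(S − S̄base)/S̄base. AUC is the trapezoidal integral from injection to
the end of the scan (no fixed early window is imposed; the window is
configurable), with endpoints interpolated so the rule stays exact for
piecewise-linear data. Maximum slope applies a centred box smoothing of
5 frames (~10 s at the native interval) — which leaves a linear ramp
invariant — then takes the maximum centred finite difference over
post-injection samples.

## Phantom and noise model

The phantom is a disk tumor at the grid centre: a necrotic, poorly
perfused core (Ktrans 0.02 min⁻¹, ve 0.10, vp 0.01), a perfused viable
rim annulus (Ktrans 0.25 min⁻¹, ve 0.35, vp 0.04), a muscle band
(Ktrans 0.08 min⁻¹, ve 0.15, vp 0.02), and signal-free background.
Pre-contrast T1 is 1800 ms in tumor and 1200 ms in muscle, magnitudes
typical for 9.4 T; all values are synthetic stand-ins, not estimates of
any particular tumor line, and are config-overridable. The default
acquisition mirrors a 20-min FLASH protocol: 610 frames at
1200/610 ≈ 1.967 s (the protocol's printed timing parameters are not
exactly mutually consistent, so total time over frame count is the
ground rule), injection at 60 s, TR 24.6 ms, 15° flip, and an 8-point
VTR ladder from 123 to 7500 ms.

Dynamic magnitude images receive Rician noise — |S + n₁ + i·n₂| with
n ~ N(0, σ) — the physically correct model for magnitude MRI; σ is set
from the target SNR defined as (noiseless rim baseline mean)/σ. The
simulated noise is checked against the analytic Rician mean
σ√(π/2)·L½(−ν²/2σ²). The high-SNR VTR ladder uses Gaussian noise by
default (Rician optional). Post-contrast T1 mapping is simulated with a
frozen residual concentration map, because a ~15-min mapping scan sees
a quasi-static residual; dynamically modelling washout during the
ladder is deliberately out of scope.

Cohort scenarios draw per-animal rim parameters from a mean-preserving
lognormal with 15% coefficient of variation (a field-typical
between-animal spread), then apply group multiplicative effects to rim
Ktrans and/or vp — e.g. a 1.5× Ktrans contrast mirroring an early
treatment-induced permeability increase. Per-animal noise streams are
spawned from the scenario seed, so cohorts are exactly reproducible.

## Statistics

ROI aggregation follows the three-ROI protocol: three non-overlapping
square ROIs in the viable rim; per parameter, the mean over valid
pixels of each ROI, then the unweighted mean of the three ROI means
(each ROI counts equally regardless of size; pixel-pooled aggregation
is available behind a flag). Group comparison gates on Shapiro–Wilk at
α = 0.05 per group: both normal → two-tailed unpaired t-test (Welch by
default, Student's optional); otherwise two-sided Mann–Whitney U (exact
null for small tie-free samples, normal approximation with continuity
correction otherwise, mid-ranks for ties). A zero-variance group makes
normality testing undefined and falls through to Mann–Whitney with a
warning. No multiple-testing correction is applied by default,
matching per-parameter reporting; Holm adjustment is available.

## Problem sizes and validation studies

The validation studies (run by `tests/test_acceptance.py` and
`scripts/acceptance.py`) use sizes chosen as a balance of statistical
resolution and desk-scale runtime:

- T1 recovery: 10 T1 values in 300–3000 ms, 100 noisy replicates each.
- Convolution, SPGR round-trip, AUC/slope oracles: dense analytic grids.
- Noiseless end-to-end recovery: 96×96 phantom, full 610-frame series,
  every rim pixel fitted.
- Noisy recovery: 500 rim pixels at Rician SNR 20, full-length series.
- Statistical calibration: 32×32 phantom, 160-frame series, 3×3-pixel
  ROIs; 200 null cohorts (type-I error) and 100 effect cohorts (power
  of the 1.5× rim-Ktrans contrast at SNR 20, n = 8 per group).

## What the phantom does and does not show

Passing these studies demonstrates correctness of the estimators on
data generated by the package's own forward models: unbiased inversion,
convergence to global minima, calibrated type-I error, and sensitivity
to the programmed effect size. Real data differ in ways the phantom
does not emulate: B0/B1 inhomogeneity, motion, partial-volume mixing at
region borders, water-exchange effects, T2* signal loss at high
concentration, a subject-specific rather than assumed AIF, and
biological heterogeneity within regions. Accuracy on real acquisitions
is therefore bounded below by, not equal to, phantom accuracy.

## Known limitations

Single-slice 2D geometry only (matching the targeted protocol); no
motion correction or registration; no 2CXM/Patlak model family; the
normality gate inherits the low power of Shapiro–Wilk at n ≤ 8, so the
t-test branch fires for mildly non-normal samples — the same behaviour
as the mirrored analysis protocol.
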