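# Methods

## Compartment model

Each phantom voxel is decomposed into four volume fractions summing to one:
`f_air` (MR-invisible: alveolar air in the lungs, non-water solids in body
tissue), intracellular water `f_ic`, extravascular-extracellular
(interstitial) water `f_ev`, and blood plasma `f_pl`. Blood-pool voxels
identify the red-cell water share with the hematocrit (`f_ic = Hct`,
`f_pl = 1 − Hct`), which makes the ECV of a blood ROI equal `1 − Hct` — the
identity the ECV formula presumes. Body voxels carry 70% water
(`f_ic + f_ev + f_pl = 0.70`) so the lung-water-density normalization, which
assumes a 70% musculoskeletal water density, is exact on the phantom. This is
also why `f_air` is defined as the *MR-invisible* fraction rather than
literal air: a body voxel's remaining 30% is solids, not gas, but both are
dark to proton imaging.

Ground truth is air-excluded, mirroring how T1-based ECV cannot see air:

* ECV = mean over the lung of `(f_ev + f_pl) / (f_ic + f_ev + f_pl)`
* PVF = mean of `f_pl / (f_ic + f_ev + f_pl)`
* ECV_extravascular = ECV − PVF (exact identity on every emitted result)
* lung water density (LWD) = mean of `f_ic + f_ev + f_pl` (air in the
  denominator), lung water volume = LWD × lung volume.

## Relaxation forward model

Fast exchange: all water in a voxel shares one R1, and each agent adds
`r1 · C · (accessible water)/(total water)` to it — the gadolinium chelate
accesses `f_ev + f_pl`, ferumoxytol only `f_pl`; in blood both access
`1 − Hct` by construction. Under this model the downstream ECV algebra
inverts the forward model exactly, which is what makes noiseless
parameter-recovery an exact oracle. Relaxivities default to r1 = 4.5
(gadolinium) and 15 L/mmol/s (ferumoxytol); they cancel in the ECV ratios,
so only the magnitude of the induced ΔR1 matters for noise realism.
Default plasma concentrations (0.2465 / 0.3806 mmol/L) place the naïve lung
at 931 → 559 ms (gadolinium) and 931 → 287 ms (ferumoxytol) with blood
1199 → ~590 / ~190 ms, the magnitudes typical for this protocol at 0.55T.
Residual gadolinium at the ferumoxytol phase is an optional confounder with
exponential clearance (terminal half-life 1.81 h), off by default since the
protocol waits ≥ 1 h.

## Scenarios and their defaults

Scenario parameters specify, per condition, the lung-mean total water
fraction and the air-excluded ECV / PVF shares, plus hematocrit, target lung
volume, and hemodynamics. Defaults reproduce the magnitudes typical for
anesthetized juvenile pigs:

| arm | water | ECV | PVF | Hct | lung vol | SV/HR | PTT |
|---|---|---|---|---|---|---|---|
| naïve | 0.33 | 64.4% | 42.2% | 0.23 | 0.93 L | 42 mL / 83 bpm | 7.5 s |
| MR baseline | 0.30 | 70% | 43% | 0.26 | 1.33 L | 46 mL / 109 | 7.3 s |
| MR regurgitation | 0.31 | 78% | 46% | 0.26 | 1.33 L | 27 mL / 122, RF 0.49 | 7.3 s |
| volume loaded | 0.32 | 73% | 51% | 0.18 | 1.26 L | 55 mL / 95 | 6.7 s |

The naïve non-air shares come from the canonical lung compartment split
(air/ic/interstitium/plasma = 55/16/10/19 as shares of the voxel), with the
total water set to 0.33 so the phantom's lung water density and volumes land
at the values this kind of study reports; the absolute 0.45-water variant
remains available through explicit parameters. Gravity is modelled as
mean-preserving linear anteroposterior ramps: plasma up posteriorly
(peak-to-peak 35% of `f_pl`) and interstitial water up anteriorly (15% of
`f_ev`), compensated by the air fraction — dependent-lung blood pooling
leaves relatively more room for interstitial fluid anteriorly, the regional
pattern such studies observe.

Between-subject variability: Gaussian subject offsets on the ECV share
(SD 4 pp), PVF share (3.5 pp), water (2 pp) and hematocrit (3 pp), shared
across the paired conditions of one subject. The regurgitation response adds
independent interstitial (SD 2 pp) and plasma (SD 5 pp) deltas; the plasma
delta moves ECV and PVF together so the extravascular share keeps its own,
tighter spread. These SDs are derived once from the variability and paired
test statistics this study design reports (a paired interstitial effect of
+5 pp at p ≈ 0.006 and n = 5 implies a paired-difference SD near 2.2 pp; the
plasma contrast at p ≈ 0.26 implies ≈ 5.3 pp).

Geometry is fixed in voxel units (body ellipse, two ellipsoidal lungs, an
LV-scale blood pool) on a 32×32×16 grid; the isotropic voxel edge is
calibrated so the lung mask hits the scenario's target lung volume
(≈ 7.2 mm for a 0.93 L lung). This coarse resolution keeps whole-cohort
simulations tractable; it under-samples the blood pool relative to a real
3.5 mm acquisition, which mainly inflates the ROI-level scatter of blood T1.

## SASHA simulation and T1 fitting

Signal model `S(TS) = A (1 − B e^{−TS/T1})` with A proportional to voxel
water content and B = 1 for ideal saturation. Sampling follows the protocol:
saturation times 104 ms × 8 averages, 200 ms × 4, 374 ms × 4, plus an
effectively fully recovered long-TS anchor (10 s × 2, configurable), on
three axial slices. Noise is complex Gaussian per average with
σ = A_voxel/SNR (SNR defined at the voxel's fully recovered signal);
averages are combined in the complex domain before the magnitude operation
(as an inline reconstruction would), so the Rician floor applies only once —
a per-average-magnitude mode exists for comparison but bakes in an
O(σ²/signal) bias no least-squares fitter can remove.

The fitter uses variable projection: for fixed T1 the model is linear in
(A, A·B), so amplitudes have a closed form and T1 reduces to a bounded 1-D
search (coarse log-spaced grid, vectorized over voxels, then a bounded
scalar polish to 1e-6 ms). Samples are weighted by √averages. Bounds:
T1 ∈ [50, 3000] ms; B ∈ [0.5, 1.1] enforced as a *box constraint* (amplitude
re-solve with B clamped at the active bound), not as a validity exclusion —
excluding B-violating voxels preferentially discards short-T1 fits and
biased short-T1 ROIs upward by several percent in development testing.
Voxels at the window edge or with non-positive amplitude are flagged
invalid; ROI T1 is the arithmetic mean of valid voxel fits (not a fit of
the ROI-mean signal).

Estimator characteristics worth knowing: the 3-parameter fit is exact on
noiseless data for any (T1, A, B) in the window, but at SNR 20 its voxelwise
distribution is right-skewed at long T1 (mean bias ≈ +2.5% at 931 ms,
median within 2%; the matched 2-parameter fit is unbiased there with half
the SD). The skew largely cancels in the ΔR1 ratios, so ECV/PVF recover
within a few tenths of a percentage point — the parameter-recovery tests
measure exactly this. The Bloch path integrates saturation → recovery →
alternating-flip bSSFP readout (80°, TR 3.0 ms, TE 1.18 ms, 43 segments,
α/2 catalyst) with closed-form relaxation between instantaneous pulses, and
the Monte-Carlo harness maps fitted-T1 bias/SD over (T1, SNR).

## Lung water and hemodynamics

Coil shading is a smooth multiplicative low-order polynomial; the correction
fits a separable polynomial (default order 2 per axis) to the body-reference
signal and divides it out. The body reference excludes the lungs, the blood
pool, and a 2-voxel dilation ring around the lungs. LWD is
`0.70 × S / median(S_body)`; values above 1.2 are flagged, never clipped. A
threshold fallback segmentation (low-signal voxels inside the filled body
outline) exists for phantoms only and is labelled as such.

First-pass curves are gamma-variates sampled at 1.5 s/frame; the LV curve is
the RV curve delayed by the true transit time so the difference of first
moments equals it exactly. The bolus defaults (α = 3, β = 1.0 s →
time-to-peak 3 s, FWHM ≈ 4.3 s) represent a compact 2 mL minibolus. The
estimator subtracts a pre-arrival baseline, truncates recirculation at 50%
of peak on the down-slope (landmarks taken on a 3-point moving average so a
single noisy frame cannot shift them), fits each curve as a gamma-variate in
the numerically stable (peak, arrival, time-to-peak, α) parameterization
with physiological bounds (α ∈ [1, 10], arrival within two frames of the
10% up-slope), and reports PTT as the difference of fitted first moments
t0 + (α+1)β. Pulmonary blood volume is PTT × cardiac output (mL/s).

Flow is a half-sine systolic waveform (systole 30% of the cycle) whose
per-beat integral equals the aortic stroke volume; beats integrate by
Simpson's rule between R-wave boundaries (or detected flow onsets walked
back through the quiescent diastole). The LV volume curve ejects the total
stroke volume `SV_aorta/(1 − RF)`, so the mitral regurgitant fraction
`(SV_LV − SV_aorta)/SV_LV` is recoverable from the pair.

## Statistics

Paired/unpaired t-tests come from scipy. The one-way repeated-measures ANOVA
computes the standard within-subject F and the Greenhouse–Geisser epsilon
from the double-centered sample covariance, ε = tr(S̃)²/((k−1)ΣS̃²), bounded
in [1/(k−1), 1] (ε ≡ 1 for two conditions), with both F degrees of freedom
scaled by ε; it matches pingouin's implementation to 1e-6 in the
cross-check test. Summary tables report mean ± SD with round-half-even
(so 105.84 renders as 106).

## Problem sizes and what the tests show

Cohort experiments use n = 5 subjects per arm on the 32×32×16 grid with
three-slice SASHA fitting; parameter-recovery sweeps 20 phantoms spanning
ECV 55–85% / PVF 30–60% (noiseless: exact; SNR 20: three noise realizations
per phantom to estimate bias); transit-time calibration uses 100 seeds at
CNR 10; the t-test calibration uses 20 000 null replicates at n = 5. Cohort
acquisitions run at SNR 40, the precision implied by the variability this
study design reports (SNR 20 alone would contribute more scatter than the
entire reported between-measurement variability); SNR 20 remains the
stress-test condition for the recovery and fitter-calibration experiments.

Passing tests show the chain is *internally* consistent: the forward model
is inverted exactly without noise, without bias beyond ~0.3 pp at SNR 20,
and the study's directional physiology survives the full measurement chain.
They do not validate the biology of real lungs: the phantom has no
respiratory or cardiac motion, no B0/B1 field effects, no partial-volume
mixing at lung boundaries beyond voxelization, no water-exchange limits
(fast exchange is assumed exactly), perfectly known masks, and
between-phase repositioning is not modelled (ROI-level analysis sidesteps
it, as the study's own design did). Known limitations besides these:
pixel-wise ECV maps are deliberately out of scope; the shading correction is
a polynomial stand-in for the scanner pipeline's correction; and the
3-parameter fitter's long-T1 skew at low SNR is intrinsic to the estimator,
not removed, only characterized.
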