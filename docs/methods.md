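# Methods

`plasmanmr` re-implements, as a tested pipeline on synthetic data, a
metabolomic workflow for differentiating Alzheimer's disease (AD) from
non-AD blood plasma using high-resolution magic angle spinning (HRMAS)
¹H NMR: spectral processing of CPMG plasma spectra, resonance
deconvolution, spectral-region quantification with pooled-control quality
control, and group-differentiation statistics built on PCA loading factors.
This note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic cohorts can and cannot show
about real data.

## Acquisition model and the simulator

A sample is a vector of latent metabolite concentrations plus three broad
lipid/macromolecule amplitudes. The free-induction decay (FID) is the sum of
decaying complex sinusoids, one per multiplet line:

    s(t) = Σ_l  A_l · exp(i(2π f_l t + φ_l)) · exp(−π w_l t)

with `f_l` from the line's chemical shift relative to the carrier (4.7 ppm,
near water) at 600 MHz, natural full width at half maximum `w_l` = 2 Hz for
metabolite lines and 120–250 Hz for the lipid components, plus a very fast
decaying component emulating the broad baseline roll, plus additive complex
Gaussian noise.

The digitization convention follows the instrument settings the pipeline
targets: 16 384 complex points at a dwell time of 1/(2·SW_Hz) with SW =
16 ppm, giving the printed 0.85 s total acquisition time. With this dwell
the digitized band spans twice the nominal width (twofold oversampling);
the analyte window 0.5–5.5 ppm sits comfortably inside, and the quoted
acquisition arithmetic (`acquisition_time`, `cpmg_mixing_time` with two
rotor periods per echo at 3600 Hz: 100 pulses → 55.56 ms) is exposed as
library functions.

Concentrations are log-normal: biology is multiplicative, so a group effect
is a shift on the log2 scale (`group_log2_effect`, AD minus non-AD, applied
half up/half down) and within-group variation is a coefficient of variation
(default 0.2 for every metabolite). The built-in library holds 19 plasma
metabolites at textbook shifts — anchored by the lactate methyl doublet
whose up-field line sits at exactly 1.32 ppm (J = 7 Hz) — with effect signs
following the reported AD directionality (sugars, glycine/serine, choline
compounds and methylated amino acids up in AD; valine, glutamine and
Krebs-cycle acids down). Some lines (choline 3.20, citrate 2.54) fall
inside the water/EDTA exclusion windows on purpose, so the exclusion logic
is exercised by realistic interferents. Numeric concentrations and effect
sizes are simulation choices, not measurements.

Per-sample acquisition errors: a chemical-shift offset (SD 0.005 ppm),
zero- and first-order phase errors (uniform within ±20° and ±10°), and
complex noise (SD 0.05 in FID units, putting the weakest library lines
near SNR ~250 and the strongest ~7500, typical of a plasma CPMG spectrum).
Each sample draws from its own counter-based random substream
(`default_rng([seed, namespace, index])`), so extending a cohort never
perturbs existing samples, and identical (config, seed) pairs are
bit-identical.

**Pooled controls** follow the physical protocol: equal plasma aliquots
from every contributor are mixed, so a pool's latent vector (metabolites
*and* lipid amplitudes) is the arithmetic mean of the contributors'
vectors; each replicate is split into aliquots and every aliquot is
re-synthesized with fresh noise, shift and phase errors, mimicking
independent acquisitions. Two replicates × three splits of a 30-sample
cohort give the six pooled controls. D₂O dilution (7.5 µL per 75 µL plasma,
10:1) is identical across pools and therefore cancels; it is not modeled
spectrally.

Clinical scores are group-shifted discretized Gaussians (AD: CDR drawn
from {0.5..3}, SoB ≈ N(6, 3), MMSE ≈ N(20, 4); non-AD: CDR mostly 0,
SoB ≈ N(0.5, 0.8), MMSE ≈ N(28.5, 1.5), all clipped to their scales), with
ages and sex ratios matching the cohort demographics the pipeline targets.
The exact distributions are free parameters of the simulator.

## Spectral processing

Fixed, logged order: exponential apodization (0.5 Hz) → first-point
scaling (×0.5, so the DFT carries no constant offset) → zero-fill ×2
(16 K → 32 K) → FFT with the axis in ppm, down-field first → phase
correction → asymmetric-least-squares baseline → chemical-shift
calibration.

**Automatic phasing.** The correction exp(−i(φ0 + φ1·f)) is estimated in
two stages. Stage 1 picks peaks on the magnitude spectrum
(phase-invariant; a 5 %-of-maximum floor keeps truncation sidelobes out)
and fits φ0 + φ1·f to the apex phase angles on the unit circle — at an
absorption peak's apex its own dispersion vanishes, so this is exact for
isolated lines; symmetric ±8-bin window sums suppress sub-bin leakage.
Stage 2 refines by minimizing real-part energy in the peak-free zones of a
high-passed copy of the complex spectrum (dispersion tails decay as
1/offset versus 1/offset² for absorption, so phase errors light those
zones up); the refinement is accepted only while it stays consistent with
the measured apex phases to within ~3°, which protects noise-free spectra
whose quiet zones are not noise-dominated. A small ridge keeps the
component of the phase ramp that the peak geometry cannot determine at
zero: with all analyte peaks inside a narrow band of the frequency axis,
φ0 and φ1 are nearly collinear, and only the effective phase *at the
peaks* is identifiable — the reported φ1 is the minimum-norm
representative. Manual offsets add to the automatic result.

**Baseline.** Whittaker smoother with asymmetric weights (p = 10⁻³,
λ = 10¹² on a 32 K grid, rescaled by (n/32768)⁴ so the smoothing length is
constant in ppm): points above the baseline get weight p, so the estimate
hugs the lower envelope. The λ default keeps the baseline slow enough to
ignore 0.2–0.5 ppm lipid humps (those belong to the deconvolution) while
following the multi-ppm baseline roll.

**Calibration.** Within ±0.1 ppm of 1.32 ppm, the two tallest local maxima
separated by 5–9 Hz are taken as the lactate methyl doublet and the ppm
axis is shifted so the up-field component's apex sits at 1.32 ppm; if no
doublet-like pair exists the tallest apex is used and a warning is logged.
No peak above 5× the noise floor raises a calibration error naming the
window.

## Deconvolution

Lineshape: pseudo-Voigt (Lorentzian–Gaussian mixture; closed-form area
h·w·[(1−η)·π/2 + η·½√(π/ln 2)]); a pure-Lorentzian mode fixes η = 0. The
fit is two-tier:

- **Broad tier** (FWHM 20–400 Hz): a morphological opening (erosion then
  dilation, 0.15 ppm window — wider than any multiplet cluster, so
  inter-line saddles are flattened) estimates the slowly varying floor.
  The sharp candidates' own Lorentzian wings (widths measured from their
  half-maximum crossings above the local floor) are subtracted, and broad
  pseudo-Voigts are fitted to what remains, on the full window. Fitting
  broad components globally keeps their support intact; slicing them
  across segments made per-sample lipid capture unstable, which propagated
  directly into pooled-QC slope noise.
- **Sharp tier** (FWHM 0.3–30 Hz): candidates are local maxima with both
  height and prominence ≥ 5× the noise σ (robust MAD estimate from the
  signal-free window −1.5 to −0.5 ppm, with a dynamic-range floor of 10⁻³
  of the tallest point so noise-free spectra do not explode into sidelobe
  candidates). The broad-subtracted signal is segmented at runs of ≥
  0.02 ppm below 2σ; segments holding more than 8 candidates are split at
  the lowest-intensity point between the central candidates so every
  least-squares problem stays small. Each segment is fitted by bounded
  trust-region least squares (analytic Jacobian; centers boxed ±0.01 ppm
  around their candidates), and lines are added greedily at the residual
  maximum while the residual norm improves by more than 2 % (at most 3
  added lines per segment). A non-converged segment is flagged and its
  candidates passed through unchanged rather than silently dropped.

Round-trip accuracy on exact pseudo-Voigt input is < 1 % residual norm;
isolated-peak recovery at SNR 50 is within 0.002 ppm (centers) and 5 %
(integrals) — the tolerances the test suite enforces.

## Regions, normalization, annotation

Peaks outside 0.5–5.5 ppm or inside the water (4.5–5.1 ppm) and EDTA
(3.55–3.68, 3.04–3.29, 2.67–2.72, 2.52–2.59 ppm) windows are removed;
boundaries count as excluded. Each sample's remaining integrals are
divided by their total, so retained normalized intensity sums to 1
exactly.

Regions are discovered from the *individual* samples only: fitted centers
are chain-clustered (single linkage, 0.01 ppm tolerance; deterministic,
down-field-first ordering), clusters present in ≥ 80 % of individuals
become regions, and bounds (cluster span ± half tolerance) are trimmed
against neighbours, the exclusion windows and the analysis window. Pooled
controls are projected onto the discovered regions but never vote — they
are aggregates of the individuals and would double-count them. A sample's
region value is the sum of its normalized integrals with centers inside
the closed interval; absence is 0, not missing, because the downstream
statistics need complete rows. A region count near ~30 for the default
cohort is data-dependent, not a contract. Regions are annotated with every
library metabolite that has a multiplet line inside them (many-to-many).

## Pooled-control QC

Each pooled control's region vector *y* is regressed (OLS with intercept;
through-origin available) on the per-region means *x* of the individual
samples; the platform is accurate when every fitted slope ("tangent") is
close to 1 (default gate |slope − 1| ≤ 0.1 — a QC gate, not a reproduction
claim). The regression p-value tests zero slope. Two caveats the test
suite demonstrates: noise confined to *y* leaves the slope unbiased, but
noise in *x* (the means) attenuates it below 1 — with 30 individuals the
mean-slope attenuation from measurement noise is ≈ 2–4 %, which bounds how
close to 1 even a perfect platform can sit; and normalization is a ratio,
so pooling (linear in concentrations) is only approximately linear in
normalized intensities. In the noise-free, variation-free limit the slope
and r² are exactly 1.

## Statistics

- **Univariate test selection** (pure function of the two samples):
  Shapiro–Wilk per group at α = 0.05; if both pass, Brown–Forsythe
  (median-centred Levene) chooses Student's t (equal variance) versus
  Welch; any non-normal group → Kruskal–Wallis. Constant groups count as
  non-normal; regions constant in both groups are flagged degenerate with
  p = 1. P-values are raw — no multiple-testing correction, matching the
  reporting convention of the workflow this reproduces; a
  Benjamini–Hochberg option exists but defaults off.
- **Clinical associations** over individuals only: global CDR (ordinal)
  by one-way ANOVA when every score group of n ≥ 3 passes normality, else
  Kruskal–Wallis; CDR-SoB and MMSE by least-squares linear fit reporting
  slope, Pearson r and p (Pearson, because the association of interest is
  linear).
- **PCA** on per-region z-scores over individuals (correlation scale: the
  loading-factor formula multiplies back by mean/SD, which presupposes
  standardized inputs), by SVD; loadings orthonormal, sign fixed so each
  component's largest-magnitude coefficient is positive; zero-variance
  regions abort with the region named (the pipeline drops them with a
  logged warning).
- **Overall loading factor** of region r for a component: loading
  coefficient × mean_r / SD_r over individuals on normalized intensities.
  The top ⌈50 %⌉ of positive factors and bottom ⌈50 %⌉ of negative factors
  (ties by region id; zeros in neither set) define the contributing
  region sets.
- **Unidirectional metabolites**: union the candidate annotations over
  each set, drop metabolites appearing in both unions. Which sign maps to
  AD is decided per component by comparing group score means.
- **ROC** on component scores: curve over all thresholds, AUC by
  trapezoid (equal to normalized Mann–Whitney U, enforced against a
  brute-force pair-concordance oracle), orientation flipped if AUC < 0.5
  (recorded), operating threshold by Youden's J, accuracy at that
  threshold.

## What the synthetic cohorts do and do not show

The simulator reproduces the statistical structure the analysis assumes —
multiplet positions, group effects, within-group variation, lipid
background, acquisition errors, pooled-control construction — so passing
tests demonstrate that the pipeline's machinery (processing, fitting,
binning, QC regression, test selection, loading factors, ROC) is correct
and calibrated. They do not validate the biology: real plasma has hundreds
of overlapping species, protein background only partially suppressed by
CPMG, field drifts, and between-run batch structure, none of which are
modeled. Two structural limitations worth knowing: unsupervised
correlation-scale PCA cannot isolate a group effect carried by a single
low-abundance metabolite (standardization equalizes variances and such an
axis has almost no correlation partners; the planted-effect recovery
property therefore uses a high-abundance species, glucose, whose shift
propagates through closure normalization into the correlation structure),
and region boundaries can cut through the center scatter of very broad
components, adding binning noise to the lipid regions — the regions whose
standard errors are largest, as expected for measurable lipids.

## Problem sizes

The default simulated study is 16 AD + 14 non-AD individuals (the pooled
subset) with 6 pooled controls at the full 16 K acquisition; one pipeline
run takes ≈ 40 s on one core. Monte-Carlo calibration suites (type-I
error, power, planted-metabolite recovery, null-ROC) run on the
simulator's concentration model feeding the statistics directly —
replicating the full spectral chain hundreds of times would add hours
without changing what those suites measure. Small-cohort integration
tests use an 8 K acquisition with 4 Hz line broadening: heavier
apodization is the standard remedy for the truncation ripple a short
acquisition would otherwise leave above the peak-picking threshold.
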