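# Methods

This note records the models, defaults and numerical choices behind the
package, and what the synthetic cohorts can and cannot say about real
data.

## Signal models

**Randomly oriented sticks.** Metabolites are assumed to diffuse freely
with diffusivity `d_intra` (μm²/ms) along one-dimensional segments whose
orientations are isotropically distributed — a caricature of neurites and
astrocytic processes that is appropriate at low SNR, where fitting a
cylinder radius as well is not supported by the data. Averaging the
mono-dimensional Gaussian signal e^(−b·d·u²) over the orientation cosine
u ∈ [0, 1] gives the powder average

    S/S0 = sqrt(π / (4 b d)) · erf( sqrt(b d) ).

For b·d < 1e-6 the implementation switches to the series
1 − bd/3 + (bd)²/10 so the b → 0 limit is exactly 1 (no 0/0). The
quadrature integral itself is kept in the test suite as an independent
oracle.

**Cumulant expansion.** The second-order expansion of the log-signal,
ln(S/S0) = −bD + (1/6)(bD)²K, defines the apparent diffusion coefficient D
and apparent kurtosis K. For powder-averaged stick data the series
converges only for b < b_c = |z₁|²/D, where z₁ ≈ 1.4506 + 1.8809i is the
first complex zero of erf (|z₁|² ≈ 5.6422, found at runtime by Newton
iteration; assuming D = 0.3 μm²/ms gives b_c ≈ 18.8 → 19 ms/μm²). The
kurtosis fit therefore uses only grid points with b ≤ b_c (b_c rounded to
3 significant figures, strict ≤), which keeps b ≤ 15.6 ms/μm² on the
default nine-point grid. In the b → 0 limit of stick data the cumulant
parameters tend to the analytic powder moments D = d/3 and
K = 3·Var(D_app)/E(D_app)² = 12/5; over the finite acquired b-range the
fitted D is compressed below d/3, which is why a +58% change in d_intra
maps to only ≈ +35% in ADC.

**Fitting.** Both models are fitted to curves normalized at the lowest
acquired b (0.4 ms/μm²); the model is evaluated as a ratio to its own
value at that reference, so no amplitude parameter is needed and the fits
are invariant to uniform rescaling. Bounded trust-region least squares is
used with d_intra, D ∈ [1e-4, 3] μm²/ms and K ∈ [−1, 10]; initialisation
D₀ from the log-slope of the first two points, K₀ = 0, d₀ = 3·D₀.
Unweighted residuals by default; the cumulant model is fitted on
ln(s_norm), i.e. log-domain noise. Standard errors come from the Jacobian
(Gauss–Newton covariance). Fits are run per animal and on the pointwise
mean of the normalized per-animal curves ("group average"); both routes
are reported. Per-animal SEs assume independent per-point noise and
ignore the shared noise of the normalization point, so they mildly
understate the spread of normalized-curve estimates.

## Synthetic cohorts

The generator emulates the acquisition chain of a paired two-timepoint,
five-animal rodent study at the default protocol (nine b-values 0.4, 1.5,
6.0, 7.6, 9.3, 13.3, 15.6, 20.8, 25.1 ms/μm² with 160, 160, 160, 160,
160, 320, 480, 480, 480 shots; δ = 6 ms, Δ = 120 ms, TE/TM = 15/112 ms,
5 kHz, 4096 complex points, 9.4 T).

**Basis.** Each metabolite is one to three Lorentzian lines at fixed
catalogue chemical shifts with areas in proton units; the default
linewidth is 6 Hz FWHM. This deliberately ignores J-evolution —
multiplets neither split nor rephase — so the basis-matched fit is exact
by construction and the chain tests estimation, not lineshape modelling.
The macromolecule background is a fixed set of broad (40–70 Hz)
Lorentzian humps, non-attenuating with b by default because its diffusion
behaviour is not specified in this setting; a toggle (`mm_attenuates`,
with `mm_d`) exists.

**Default ground truth.** Week-0 concentrations (mM-equivalent): Gln 4.0,
Glu 9.0, Ins 5.8, Tau 6.0, NAA 8.5, tCr 8.0, tCho 1.4. Week-6/week-0
concentration ratios encode the disease contrast: Gln ×2.78 (+178%), Ins
×0.71 (−29%), with mild decreasing trends for the others. Week-0
intra-stick diffusivities are 0.37–0.42 μm²/ms, chosen so the
restricted-range cumulant fit yields week-0 ADCs ≈ 0.10–0.12 μm²/ms,
typical of healthy rodent brain; the week-6 diffusivity ratios are Gln
×1.58 (+58%), Ins ×1.45, tCho ×1.32, Tau ×1.26, and 1.10–1.15 for
NAA/tCr/Glu. Through the finite-b cumulant fit these propagate to ADC
changes of ≈ +35% (Gln), +29% (Ins) and +18% (Tau), and to a mild
kurtosis decrease, without any separate ADC dial.

**Variability.** All animal-level variability is mean-preserving
log-normal: CV 0.08 on week-0 concentrations, 0.06 on week-0
diffusivities, and per-metabolite CVs on the week-6/week-0 effect ratios
(e.g. 0.34 on the Gln concentration ratio, 0.10 on its diffusivity ratio)
sized so the across-animal SDs of recovered percent changes match the
dispersions such a cohort realistically shows. The paired design is
meaningful because each animal keeps its own baseline.

**Noise and SNR.** Complex Gaussian noise is added per shot in the time
domain. Its SD is calibrated so the shot-averaged lowest-b spectrum
reaches a target spectral SNR of 60, defined as the maximum real peak in
the 0.5–4.2 ppm window divided by the real-part noise SD of the averaged
spectrum. Note the LCModel convention divides the peak by *twice* the RMS
noise, so this corresponds to an LCModel-style S/N of ≈ 30, the middle of
the 15–45 range typical of in vivo diffusion spectra. Because the
calibration fixes the *averaged* SNR at the lowest b, reduced-shot test
protocols keep the same spectral quality.

**Artifacts.** Cumulative phase drift (0.002 rad/shot), cumulative
frequency drift (0.02 Hz/shot) and Bernoulli amplitude dropouts
(p = 0.01, depth 0.7) are injected per shot. These represent slow scanner
drift and translational-motion-like signal loss; rotational/compressive
motion is represented only through dropouts.

**One seed.** Every random draw flows from a single root seed through
named seed sequences, so a cohort is reproducible and shots can be
regenerated lazily per animal/timepoint without holding the full
shot-level dataset (~1.7 GB complex) in memory.

## Preprocessing

Shots at one b-value are aligned to the pointwise-median spectrum:
frequency offsets by magnitude cross-correlation over a reference window
(0.5–4.2 ppm) with parabolic sub-bin interpolation, then zero-order phase
from the complex inner product with the reference. All-zero shots are
flagged and left untouched. Eddy-current distortion is not simulated; its
zero-order component would be absorbed by the phase alignment, and no
water-reference correction is implemented.

Outlier shots with manifest signal drops are removed before averaging. A
raw magnitude integral is a poor drop detector at realistic per-shot SNR
(rectified noise dominates the integral), so the per-shot signal level is
measured by a matched filter — the real part of the inner product with
the median spectrum over the window, normalized to score ≈ 1 for the
median shot — and a shot is removed iff its relative amplitude falls
strictly below 1 − drop_threshold (default 0.5, i.e. a > 50% drop; an
exactly-50% drop is retained). The median reference makes the criterion
robust to the outliers themselves and order-invariant; it also means a
*majority* of corrupted shots cannot be flagged (they drag the median
down), which is the honest failure mode of any median-referenced rule.

After averaging, the mean spectrum is registered globally: a coarse
frequency shift against the basis-derived reference spectrum, then —
inside the quantification step — a model-based refinement in which a
sub-bin referencing shift and the zero-order phase are chosen to minimize
the linear-model residual (for a fixed shift the optimal phase is the
smallest eigenvector of a 2×2 projected-residual form). This mirrors how
linear-combination packages co-fit referencing and phase.

## Quantification and CRLB

The averaged spectrum's real part over 0.5–4.2 ppm is fitted as a
non-negative linear combination of the metabolite and macromolecule basis
spectra plus an unconstrained Legendre baseline (order 2). The solution
is exact: the baseline columns are projected out, the signal amplitudes
solved by active-set NNLS, and the baseline back-substituted. A collinear
basis pair (normalized correlation > 0.9995) raises an error naming the
pair.

Because the lineshape is fixed, the amplitude CRLBs follow from the
linear-model Fisher information: CRLB_m = σ·sqrt[(AᵀA)⁻¹]_mm, reported
relative to the amplitude in percent (zero amplitude → ∞, flagged). σ is
estimated from a signal-free region (7–10 ppm, first-difference
detrended). This is a simplification of full nonlinear-CRLB machinery and
is exact only conditional on the fixed lineshape.

Reporting rules select metabolite *names*, never individual values: the
concentration series keeps a metabolite iff its CRLB is below 25% at week
0 for every animal; the diffusion series iff below 6% at the lowest
b-value for every animal at both timepoints (strict comparisons). At the
default SNR all seven reported metabolites pass the 6% rule with margin.

## Cohort statistics

The long parameter table holds, per animal × timepoint × metabolite:
concentration (the quantified amplitude at b = 0.4; no water/T2 scaling,
so units are arbitrary), d_intra from the sticks fit, and ADC/kurtosis
from the restricted cumulant fit. Each parameter is analysed with a
classical univariate two-way repeated-measures ANOVA (disease ×
metabolite, both within-subject, subject as block): each effect is tested
against its own subject-interaction mean square, and a Prism-style
"subject-matching" line tests the subject mean square against the
residual. No sphericity correction is applied. Post-hoc per-metabolite
disease comparisons use a pooled within-subject error (disease×subject
plus residual sums of squares) by default, or a plain paired t per
metabolite (`posthoc="paired"`); raw p-values are Bonferroni-multiplied
by the number of retained metabolites (7 for the diffusion series) and
capped at 1. All tests are two-tailed.

## Numerical and design notes

* The concentration readout is the amplitude at b = 0.4, not an
  extrapolation to b = 0. When diffusivity increases at week 6 the
  reference-b amplitude is slightly more attenuated, so a configured
  ×2.78 Gln concentration ratio is recovered as ≈ +170% rather than
  +178% — an intentional property of reading concentrations off a
  diffusion-weighted point.
* At high b the per-shot metabolite signal approaches the noise, and
  aligning shots to the median with noisy phase estimates loses a little
  coherent amplitude; absolute D_intra is therefore overestimated by
  ~5–10% at the default SNR, while within-animal *changes* — the study
  readout — are recovered essentially unbiased.
* Shot-level dropout detection is statistical: at default settings ~1.2%
  of shots are removed against a 1% true dropout rate (the excess being
  borderline noise cases); undetected sub-threshold dropouts bias
  amplitudes by well under 1%.
* Problem sizes: the test suite exercises the full nine-b protocol with
  reduced shot counts (8–24) and a 2048-point grid, plus two full-size
  cohorts in the acceptance tests; the acceptance script averages the
  stochastic targets over 20 full-size cohorts. These sizes are the
  package's choice of a precision/runtime trade-off; the defaults always
  remain the full protocol.

## What passing tests do and do not show

The simulator shares its attenuation law, basis shapes and noise model
with the fitting chain, so parameter recovery demonstrates the
correctness and calibration of the estimation pipeline — not that the
sticks model describes real tissue. Real spectra add J-coupled multiplet
evolution, lineshape distortion, residual water, eddy currents,
first-order phase errors, motion beyond drift/dropout, relaxation
weighting and basis imperfection, none of which are emulated. Conclusions
about real cohorts should lean on the model-agnostic parts (preprocessing
robustness, CRLB filtering, statistics) and treat the recovery results as
an upper bound on fidelity.
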