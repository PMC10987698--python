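# dwmrs

Simulation and analysis of **diffusion-weighted MR spectroscopy (dMRS)** of
brain metabolites, built around a paired longitudinal rodent design: each
animal is scanned healthy ("week 0") and again in disease ("week 6"), and
the diffusion behaviour of the major brain metabolites — glutamine (Gln),
glutamate (Glu), myo-inositol (Ins), taurine (Tau), NAA, total creatine
(tCr) and total choline (tCho) — is compared within subject.

Because metabolites are almost exclusively intracellular, their diffusion
reports on cell-interior geometry (neurites, astrocytic processes) rather
than on the extracellular space probed by water diffusion MRI. The package
targets the hepatic-encephalopathy use case — a large brain glutamine
increase with osmotic release of Ins/Tau/tCho and altered cell
microstructure — but every stage is generic.

## What it does

1. **Simulate** shot-level complex spectra for a whole cohort: Lorentzian
   metabolite basis + macromolecule background, per-b diffusion attenuation
   from the randomly-oriented-sticks model, shot-to-shot phase/frequency
   drift, amplitude dropouts and complex Gaussian noise. Nine b-values
   (0.4–25.1 ms/μm², 160–480 shots each, δ = 6 ms, Δ = 120 ms, 5 kHz /
   4096 points) form the default protocol.
2. **Preprocess** the shots: spectral-registration alignment to the median
   shot, matched-filter screening of shots with manifest (>50%) signal
   drops, and averaging per b-value.
3. **Quantify** each averaged spectrum by a non-negative linear-combination
   fit against the basis, with relative Cramér–Rao lower bounds (CRLB) and
   the reporting rules: CRLB < 25% at week 0 (concentration series) or
   < 6% at the lowest b-value (diffusion series), for **all** animals.
4. **Fit** each metabolite's normalized decay S(b)/S(0.4) per animal and on
   the group average:
   * randomly oriented sticks (powder average):
     S/S₀ = √(π/(4 b D_intra)) · erf(√(b D_intra)),
   * second-order cumulant expansion:
     ln(S/S₀) = −b·D + (1/6)(b·D)²·K,
     restricted to b ≤ b_c = |z₁|²/D with z₁ the first complex zero of the
     error function (b_c ≈ 19 ms/μm² for D = 0.3 μm²/ms, so the grid keeps
     b ≤ 15.6).
5. **Cohort statistics**: per-animal percent changes and a two-way
   repeated-measures ANOVA (disease × metabolite, subject-blocked) with
   Bonferroni-corrected per-metabolite post-hoc tests.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (seed 1) and write their tables to `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_quantify.py
python analysis/03_fit_diffusion.py
python analysis/04_cohort_stats.py
```

`02` reports the spectral quality, e.g. the worst relative CRLB at
b = 0.4 ms/μm² per metabolite (all seven stay below the 6% cut):

```
rejected 302 outlier shots across 90 spectra
worst relative CRLB (%) at the lowest b-value, per metabolite:
Gln 2.07  Glu 1.14  Ins 1.86  NAA 0.99  Tau 1.86  tCho 2.51  tCr 0.91
retained by the dmrs CRLB rule: Gln, Glu, Ins, NAA, Tau, tCho, tCr
```

`04` prints the disease contrasts; for this seed (mean ± SD over the five
animals, `*` = Bonferroni-adjusted p < 0.05):

```
== conc ==      Gln: +189.3 ± 140.3 % *   Ins: -32.5 ± 16.0 %
== d_intra ==   Gln:  +49.6 ±   9.4 % *   Ins: +49.6 ± 30.5 % *  Tau: +28.8 ± 20.1 % *
== adc ==       Gln:  +32.2 ±   6.3 % *   Ins: +29.1 ± 19.0 % *  Tau: +21.8 ±  9.9 % *
== kurtosis ==  Gln:   -6.5 ±   7.9 %     (overall decreasing trend, n.s.)
```

i.e. the week-6 brain shows the expected large glutamine accumulation,
osmolyte depletion, faster metabolite diffusion (both D_intra and ADC) and
a mild, non-significant kurtosis decrease.

The same pipeline is scriptable as a CLI (`dwmrs simulate | preprocess |
quantify | fit | stats | run-all`), all stages exchanging documented
CSV/JSON files.

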