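# Methods

## The transform

A phased 1D ¹H NMR spectrum carries two channels per frequency point: the
absorption mode A(δ) and the dispersion mode D(δ).  For a Lorentzian line
of unit area, half-width γ (in ppm) centred at δ₀,

    A(δ) = (1/π) · γ / ((δ−δ₀)² + γ²),
    D(δ) = (1/π) · (δ−δ₀) / ((δ−δ₀)² + γ²),

an exact Hilbert pair.  The SMolESY representation is S(δ) = |dD/dδ|,
computed by central differences on the uniform ppm grid (one-sided at the
two edges).  Closed-form consequences, all used as test oracles:

* peak amplitude 1/(πγ²): suppression of broad lines scales as
  (γ_broad/γ_narrow)², which removes the macromolecular background
  without any baseline model;
* the full width at half maximum of the central lobe solves
  u² + 4u − 1 = 0 with u = (δ/γ)², giving FWHM(S)/FWHM(A) = 0.4859;
* |dD/dδ| has side lobes of 12.5 % of the main lobe peaking at ±√3·γ —
  these matter for peak picking (below);
* the central lobe touches zero at ±γ, so side lobes are fully prominent
  and cannot be removed by prominence filtering.

At 600 MHz the serum small-molecule regime corresponds to SMolESY full
widths of 0.0009–0.0011 ppm; the package uses the upper figure
(`NOMINAL_SMOLESY_LINEWIDTH = 0.0011` ppm) as the instrument-class
linewidth from which all assignment and integration window sizes are
derived.  Via the 0.4859 ratio this figure corresponds to absorption
linewidths of ≈1.1–1.4 Hz.  Whether the derivative is taken with respect
to ppm or to the point index differs only by a global positive constant
and cancels from all relative quantities.

## Denoising, noise floor, peak picking

Inside configurable windows — by default the aromatic region
(6.5–8.7 ppm) and the near-water band (4.3–5.1 ppm), where tyrosine,
phenylalanine, histidine and formate are weak — an 11-point unweighted
centred moving average is applied; the kernel shrinks symmetrically at
window boundaries.  On white noise the filter reduces sigma by ≈1/√11.

The noise floor is estimated in a signal-free region (9.55–9.95 ppm by
default) with a MAD-based robust estimator.  Because SMolESY intensities
are magnitudes, the noise there is half-normal; the estimator divides the
MAD by 0.39894 (the half-normal MAD in units of the underlying normal
sigma) so that it reports the sigma of the *signed* derivative noise,
which for channel noise of sd s on a grid of step h is s·√2/(2h).

Peaks are strict local maxima above `min_snr` (default 5) times the noise
sigma, refined to sub-grid positions by 3-point parabolic interpolation.
A peak is discarded as a derivative side lobe when a ≥4× taller peak lies
0.0015–0.0045 ppm away (the ±√3·γ band for 1–2 Hz lines); parent
candidates are searched slightly beyond the window edge so the rule does
not depend on window placement.  No default-panel multiplet has genuine
component spacings inside that band (all J ≥ 3.8 Hz ⇒ ≥0.0063 ppm).

## Calibration

The δ axis is referenced to the α-glucose anomeric proton doublet at
5.233 ppm, the standard reference in blood ¹H NMR.  Within a 5.15–5.32 ppm
search window the calibrator picks the peak pair whose separation matches
J = 3.8 ± 0.8 Hz (literature value; the panel file owns it) and whose
heights agree within a factor two, preferring the tallest such pair, and
subtracts (centre − 5.233) from the axis.  The shift is a pure
relabelling — no interpolation, hence exactly invertible and idempotent to
within one grid step.  Calibration operates on the SMolESY representation
rather than the raw absorption because the derivative sharpens the
doublet and flattens the residual background near it.  A spectrum without
a credible doublet is processed anyway with every result flagged
`uncalibrated`.

## Assignment

The panel is declarative YAML: per spin system a metabolite name, nominal
δ, coarse window, multiplicity, J, proton count, assignment strategy and
integration component selection.  The shipped panel has 22 metabolites /
24 spin systems (creatinine CH₃+CH₂ and valine's two CH₃ doublets are the
two-system metabolites); windows and J values follow standard serum
assignment tables and everything is user-editable.

**Multiplets** (strategy `pattern`): among picked peaks in the coarse
window, candidate component sets must have adjacent spacings within
max(0.3 Hz, 15 % of J)/SF of J/SF and heights consistent with the
binomial pattern (1:1, 1:2:1, 1:3:3:1) within a factor two — deliberately
loose, because the transform distorts component heights when widths
differ.  Sets are ranked by

    score = spacing_err + 0.25 · ratio_err + 0.3 · (1 − Σh/Σh_max),

with ties broken by proximity to the window centre, then by summed
height.  The spacing term dominates because J is the hard physical
constraint; the height-deficit term exists because near-noise decoy sets
can be perfectly J- and ratio-regular (noise has no reason to be
asymmetric) yet many-fold weaker than the true multiplet.

**Correlation singlets** (glycine, creatine, creatinine CH₃/CH₂, choline,
dimethyl sulfone, methionine, histidine): singlet positions drift with pH
and ionic strength, but the drift is largely a shared sample-level
effect.  Per cohort, ordinary least squares fits
δ_target = a·δ_ref + b for each reference (the lactate and alanine methyl
doublets, themselves assigned by pattern); a new spectrum predicts each
singlet's position from its own observed references (predictions
averaged) and searches only

    predicted ± clamp(2·residual_sd, 1.5·lw, 2.5·lw),   lw = 0.0011 ppm,

i.e. a window of 3–5 SMolESY linewidths, intersected with the coarse
window.  With the synthetic cohort's jitter the residual floor applies
and the refined glycine window is 0.0033 ppm — under the 0.004 ppm
figure that window narrowing is expected to reach at 600 MHz.  Untrained
or reference-less spectra fall back to the coarse window with
`unrefined`/`low_confidence` flags.

**Training** harvests observations from a cohort: references by strict
pattern matching, targets as the tallest ≥10·sigma peak in a seed window
of ±`bootstrap_halfwidth` (default 0.005 ppm, ±0.012 for the strongly
pH-sensitive histidine) around the nominal δ.  The OLS fit performs one
robust refit after discarding residuals beyond 4× the MAD sigma, because
a bootstrap harvest can contain occasional wrong peaks.  At least 20
paired observations are required per model; fewer leaves the target
untrained.  The shipped `models_default.tsv` was fitted to a 100-sample
synthetic cohort (`examples/train_default_models.py` regenerates it);
real deployments retrain with `smolesy train`.

**Narrow windows**: acetone/acetate (≤0.006 ppm) and formate
(≤0.008 ppm) windows are narrow enough after glucose calibration to need
no correlation; the tallest in-window peak is taken.

**Cross-check**: creatinine's CH₃ and CH₂ singlets must satisfy the
cohort-fitted intramolecular relation δ_CH2 = m·δ_CH3 + b within 3
SMolESY linewidths; otherwise the lower-s/n member is demoted with
`crosscheck failed`.  A lone member survives with `partial_evidence`.

## Quantification

Assigned components are integrated by trapezoid over ±3 SMolESY
linewidths (±0.0033 ppm) around each selected component and summed; there
is no baseline subtraction because the representation suppresses the
baseline by construction.  Component selection per system (`all`,
`outer`, `tallest`, `leftmost`, `rightmost`) exists for crowded regions;
the per-proton normalisation divides by the proton count pro-rated by the
binomial weight fraction of the integrated components (one component of a
CH₃ doublet ⇒ 1.5 effective protons), keeping partial-multiplet readouts
comparable across samples.  Relative concentrations are arbitrary-unit,
scale-equivariant quantities; nothing in the package claims mmol/L.

The QC overlay (`align_assigned_features`) translates each assigned
system to a per-window anchor — the window centre by default, or a
seeded-random position for cohort overlays — so misassignments stand out
visually; unassigned systems are left in place.  Anchoring is
deterministic unless a seed explicitly requests randomisation.

Numerical note: at the default grid (65536 points over 20 ppm,
h ≈ 3.05·10⁻⁴ ppm) the trapezoid integral of an analytic SMolESY line
agrees with dense quadrature over the same span to ~0.5–0.8 %; the error
is dominated by the integrand's kinks at ±γ (O(h²·|Δf′|)) and is a
common-mode factor that cancels from all relative comparisons.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline exploits,
with defaults chosen as a typical 600 MHz serum study:

* grid 65536 points, 14.8 → −5.2 ppm, SF 600.13 MHz;
* per-metabolite base concentrations proportional to typical serum
  abundances (glucose 5.0 … choline 0.02, arbitrary units), scattered
  log-normally with sd(log) = 0.4 per sample;
* absorption linewidths uniform in 1.9–2.2 Hz per line;
* chemical shifts δ = base + loading·latent + ε with a per-sample latent
  factor (sd 1) proxying pH/ionic strength and ε of sd 0.0003 ppm; the
  lactate/alanine loadings (0.0020/0.0024 ppm) are ~2.5× those of the
  correlated singlets, giving e.g. a glycine-on-lactate slope of 0.4 and
  shift correlations ≥0.9, and histidine carries the largest loading
  (0.0025) as the classic pH-sensitive resonance; the glucose reference
  does not drift beyond ε, as befits the calibration anchor;
* a macromolecular envelope of seven broad Lorentzians (200–400 Hz wide,
  absorption amplitudes 0.5–1.5) anchored at lipoprotein/glycoprotein/
  albumin positions — by area it rivals the whole metabolome, and after
  the transform it perturbs every panel integral by <0.5 % (asserted by a
  paired with/without test);
* white Gaussian noise (sd 0.02) on both channels, an exactly zeroed
  4.6–4.9 ppm water band, and a complete ground-truth sidecar per line.

Standard-addition series reuse one frozen base sample and scale only the
target metabolite by (1 + level), so linearity is probed against an
identical background and noise realisation, as in a real spiking
experiment on aliquots of one specimen.

What the generator does **not** emulate — strong coupling (roofing),
lipoprotein lineshape detail, field/temperature drift within a cohort,
imperfect phasing, residual water distortions — bounds what green tests
prove: they validate the algorithmic machinery under the stated
statistical structure, not performance on any real cohort.  Real serum
additionally contains many non-panel resonances; the matcher's decoy
handling is exercised only through noise, side lobes and the deliberate
window crowding around 0.9–1.05 and 3.02–3.07 ppm.

## Design choices on genuinely open points

* Coarse singlet windows are ≥0.01 ppm wide and the creatine/creatinine
  coarse windows deliberately overlap: the generator's jitter makes the
  coarse windows ambiguous while refined windows are not — the regime
  the correlation strategy exists for.
* The isoleucine triplet sits at 0.92 ppm, clear of the leucine doublet:
  analysis of a failing draw showed a 2σ-strong leucine tail can cancel
  a 3σ-weak isoleucine outer component outright by dispersion-derivative
  interference, which no matcher can repair under the strict
  component-count contract.
* Assignment accuracy bookkeeping counts a spin system correct when
  assigned within 0.002 ppm (~2 absorption linewidths) of truth; missed
  and misplaced assignments are pooled as failures.
* Determinism everywhere: fixed tie-break order (score, window-centre
  proximity, summed height), seeded randomness only where explicitly
  requested, byte-identical batch outputs.

## Problem sizes

The shipped validation workloads are sized for a laptop-class single
core: 200-sample cohorts for accuracy and window statistics, 100 samples
for the shipped models, 5-level spiking series per metabolite.  A full
acceptance run regenerates everything in well under a minute; per
spectrum, transform + assignment + integration takes ~30 ms at 65536
points.

## Known limitations

* First-order multiplets only; strong coupling is out of scope.
* The correlation models are linear and per-cohort; they do not transfer
  across field strengths or matrices and must be retrained.
* Quantification is relative; absolute units require external
  calibration, deliberately not modelled.
* The Bruker reader covers the processed-1D subset (`1r`/`1i`/`procs`,
  int32 or float64, both byte orders) — no FID processing, no JCAMP-DX.
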