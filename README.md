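# smolesy

Targeted metabolite panel measurements from standard 1D ¹H NMR spectra of
serum and plasma — no CPMG experiment, no lineshape deconvolution, no
baseline fitting.

Blood ¹H NMR profiles bury sharp small-molecule resonances under a broad
macromolecular background (lipoproteins, glycoproteins, albumin).  This
package implements SMolESY (Small Molecule Enhancement SpectroscopY)
selection: the magnitude of the first derivative of the *dispersion*
(imaginary) channel of a phased spectrum,

    S(δ) = | d Im s(δ) / dδ |.

For a Lorentzian line of half-width γ the dispersion derivative peaks at
1/(πγ²): a line's SMolESY amplitude falls with the **square** of its
width, so a 100 Hz macromolecular hump is suppressed 10⁴-fold relative to
a 1 Hz metabolite line of equal area, while metabolite linewidths shrink
to ≈0.486 of their absorption width.  On that representation the pipeline

1. **calibrates** the δ axis to the glucose anomeric doublet at 5.233 ppm
   (J ≈ 3.8 Hz) by exact axis relabelling;
2. **assigns** 24 spin systems of 22 metabolites: multiplets by J-coupling
   pattern matching (spacing J/SF, binomial height ratios), singlets by
   cohort-trained linear correlations with the lactate/alanine methyl
   doublets that shrink their search windows to 3–5 SMolESY linewidths
   (glycine ≤0.004 ppm at 600 MHz), acetone/acetate/formate by fixed
   narrow windows, and creatinine by an additional intramolecular
   CH₃↔CH₂ shift cross-check;
3. **integrates** the selected components directly (trapezoid over ±3
   SMolESY linewidths, no baseline model) and normalises to one proton,
   yielding *relative* concentrations in arbitrary units.

An 11-point moving average denoises designated noisy windows (aromatic
region, near the water band) before assignment.  A synthetic-spectrum
module generates serum-like cohorts (Lorentzian multiplets with exact
Hilbert-pair dispersion, broad macromolecular envelope, correlated
chemical-shift jitter via a latent pH-like factor, channel noise, zeroed
water band) with full ground truth, so every stage is testable end to end.

## Worked example

```sh
python examples/standard_addition.py
```

```
spiking alanine at levels [0.0, 0.5, 1.0, 2.0, 4.0]
  level 0.0: relative concentration      80.52
  level 0.5: relative concentration     120.79
  level 1.0: relative concentration     161.07
  level 2.0: relative concentration     241.62
  level 4.0: relative concentration     402.71
linear fit: slope 80.55, R^2 = 1.000000
```

Alanine is spiked into one fixed synthetic serum sample; the reported
per-proton integral rises linearly with the amount added (R² ≈ 1), and the
intercept is the base sample's own alanine content.  `examples/` holds
similar narrative scripts for the transform itself (`transform_demo.py`),
cohort quantification (`quantify_cohort.py`), and retraining the shipped
correlation models (`train_default_models.py`).

## Library and command line

The package is primarily a library:

```python
from smolesy import load_panel, load_models, quantify_panel, read_bruker_1d

panel = load_panel()            # 22 metabolites / 24 spin systems (YAML)
models = load_models()          # shipped singlet-correlation models
spectrum = read_bruker_1d("sample/pdata/1")   # needs 1r, 1i and procs
measurements, assignment = quantify_panel(spectrum, panel, models)
```

A thin `smolesy` CLI wraps the same functions for batch use:

```sh
smolesy simulate --mode cohort --n 50 --seed 1 --out cohort/
smolesy train    --input 'cohort/sim-*.tsv' --out models.tsv
smolesy quantify --input 'cohort/sim-*.tsv' --models models.tsv --out results/
smolesy transform --input sample.tsv --out smolesy/
```

`quantify` writes one CSV row per (sample, metabolite) with the relative
concentration, assignment flag, QC flags and the applied calibration
shift; unassigned values are left empty, never written as zero.  Spectra
are read either from Bruker processed-data directories (`1r`/`1i`/`procs`)
or from a plain tab-separated text dialect; both channels of the phased
signal are required, since the transform differentiates the dispersion
part.

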