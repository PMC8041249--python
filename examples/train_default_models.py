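"""Train the shipped default correlation-model store on a synthetic cohort.

The singlet-window narrowing needs per-cohort linear models relating each
singlet's chemical shift to the lactate/alanine doublet shifts.  Real
deployments retrain on their own cohort (``smolesy train``); the package
ships defaults fitted to a 100-sample synthetic cohort so the pipeline is
runnable out of the box.  Running this script regenerates
``src/smolesy/data/models_default.tsv``.
"""

from pathlib import Path

from smolesy import (CohortSpec, collect_training_observations,
                     fit_correlation_models, load_panel, save_models,
                     simulate_cohort)

SEED = 20260928
N = 100

panel = load_panel()
spectra, _ = simulate_cohort(N, panel, CohortSpec(), seed=SEED)
obs = collect_training_observations(spectra, panel)
models, untrained = fit_correlation_models(obs, panel)
assert not untrained, f"untrained targets: {untrained}"

dest = Path(__file__).resolve().parents[1] / "src" / "smolesy" / "data" / "models_default.tsv"
save_models(models, dest)
print(f"wrote {len(models)} models ({N}-sample synthetic cohort, seed {SEED})")
print(f"-> {dest}")
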