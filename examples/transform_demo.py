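"""Derivative-based macromolecule suppression on one synthetic serum spectrum.

Builds a serum-like spectrum (metabolite multiplets + broad macromolecular
envelope), applies the SMolESY transform, and prints how strongly the broad
background is suppressed relative to a sharp metabolite line — the property
that lets the pipeline integrate directly with no baseline fitting.
"""

import dataclasses

import numpy as np

from smolesy import CohortSpec, load_panel, smolesy_transform
from smolesy.synthetic import draw_sample_spec, simulate_sample

panel = load_panel()
cohort = CohortSpec()
rng = np.random.default_rng(0)
spec = dataclasses.replace(
    draw_sample_spec(rng, panel, cohort, "demo"), noise_sd=0.0)

with_env, _ = simulate_sample(spec, panel, cohort.grid, cohort.water_band)
without_env, _ = simulate_sample(spec, panel, cohort.grid, cohort.water_band,
                                 with_envelope=False)

# absorption mode: envelope area vs total metabolite area near 1.3 ppm
sl = with_env.window_slice(0.7, 2.6)
env_area = np.trapezoid(with_env.real[sl] - without_env.real[sl],
                        with_env.ppm[sl])
met_area = np.trapezoid(without_env.real[sl], without_env.ppm[sl])
print(f"0.7-2.6 ppm absorption area, macromolecules/metabolites: "
      f"{abs(env_area / met_area):.2f}")

sm_with = smolesy_transform(with_env)
sm_without = smolesy_transform(without_env)
resid = np.abs(sm_with.intensity[sl] - sm_without.intensity[sl]).max()
peak = sm_without.intensity[sl].max()
print(f"after SMolESY, max envelope residual is {100 * resid / peak:.3f}% "
      f"of the tallest metabolite line in the same region")
print("-> a background that would bias every raw absorption integral is "
      "reduced to noise level in the derivative representation")
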