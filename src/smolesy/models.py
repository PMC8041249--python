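"""Chemical-shift correlation models for singlet assignment windows.

Singlet positions in serum/plasma drift with pH and ionic strength, and
several singlet coarse windows (>= 0.01 ppm) are wide enough to admit the
wrong neighbour.  But the drift is largely a shared, sample-level effect:
the position of a singlet co-varies with the positions of the abundant
lactate and alanine methyl doublets, which are themselves assigned
unambiguously by J-pattern matching.  Fitting, per cohort, a linear map

    delta_target = slope * delta_reference + intercept

per (target, reference) pair lets each new spectrum predict where its
singlets must be and shrink the search window to a few SMolESY linewidths.

The models are ordinary least squares fits; the refined half-window is

    halfwidth = clamp( min(2.5 * lw, 2 * residual_sd), floor = 1.5 * lw )

with ``lw`` the nominal SMolESY full width at half maximum (0.0011 ppm at
600 MHz), so the full refined window spans 3-5 SMolESY linewidths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MetabolitePanel
from .transform import NOMINAL_SMOLESY_LINEWIDTH

__all__ = [
    "CorrelationModel",
    "ModelSet",
    "fit_correlation_models",
    "collect_training_observations",
    "window_halfwidth",
    "save_models",
    "load_models",
    "MIN_TRAINING_OBSERVATIONS",
]

MIN_TRAINING_OBSERVATIONS = 20


@dataclass(frozen=True)
class CorrelationModel:
    """delta_target = slope * delta_reference + intercept (all in ppm)."""

    target: str
    reference: str
    slope: float
    intercept: float
    residual_sd: float

    def predict(self, delta_reference: float) -> float:
        return self.slope * delta_reference + self.intercept


def window_halfwidth(
    residual_sd: float,
    linewidth: float = NOMINAL_SMOLESY_LINEWIDTH,
) -> float:
    """Refined-window halfwidth in ppm: 1.5-2.5 SMolESY linewidths."""
    return float(np.clip(2.0 * residual_sd, 1.5 * linewidth, 2.5 * linewidth))


class ModelSet:
    """Trained correlation models indexed by target system."""

    def __init__(self, models: list[CorrelationModel] | None = None):
        self._by_target: dict[str, list[CorrelationModel]] = {}
        for m in models or []:
            self._by_target.setdefault(m.target, []).append(m)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_target.values())

    def for_target(self, system_id: str) -> list[CorrelationModel]:
        return list(self._by_target.get(system_id, []))

    def is_trained(self, system_id: str) -> bool:
        return system_id in self._by_target

    def pair(self, target: str, reference: str) -> CorrelationModel | None:
        for m in self._by_target.get(target, []):
            if m.reference == reference:
                return m
        return None

    def all_models(self) -> list[CorrelationModel]:
        return [m for v in self._by_target.values() for m in v]

    def predict(self, system_id: str, ref_deltas: dict[str, float]):
        """Averaged prediction and halfwidth for a target given observed refs.

        Returns ``(predicted_ppm, halfwidth_ppm)`` or ``None`` when no model
        has an observed reference in ``ref_deltas``.
        """
        preds, sds = [], []
        for m in self.for_target(system_id):
            if m.reference in ref_deltas:
                preds.append(m.predict(ref_deltas[m.reference]))
                sds.append(m.residual_sd)
        if not preds:
            return None
        return float(np.mean(preds)), window_halfwidth(float(max(sds)))


def fit_correlation_models(
    observations: pd.DataFrame,
    panel: MetabolitePanel,
    min_obs: int = MIN_TRAINING_OBSERVATIONS,
) -> tuple[ModelSet, list[str]]:
    """OLS fit per (correlation target, reference) from cohort observations.

    ``observations`` has columns ``sample``, ``system_id``, ``delta`` —
    one confidently assigned position per spin system per spectrum.
    Cross-check partners (e.g. creatinine CH2 against CH3) are fitted the
    same way and stored in the same set.

    Returns the trained set and the list of system_ids left untrained for
    lack of paired observations (< ``min_obs``).
    """
    wide = observations.pivot_table(
        index="sample", columns="system_id", values="delta", aggfunc="first"
    )
    models: list[CorrelationModel] = []
    untrained: list[str] = []
    for sdef in panel.systems:
        pairs: list[tuple[str, str]] = []
        if sdef.strategy == "correlation":
            pairs += [(sdef.system_id, r) for r in sdef.correlation_refs]
        if sdef.crosscheck is not None:
            pairs.append((sdef.system_id, sdef.crosscheck))
        fitted_any = False
        for target, ref in pairs:
            if target not in wide.columns or ref not in wide.columns:
                continue
            sub = wide[[target, ref]].dropna()
            if len(sub) < min_obs:
                continue
            x = sub[ref].to_numpy()
            y = sub[target].to_numpy()
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            # one robust refit: bootstrap harvests can contain occasional
            # wrong-peak observations, which would inflate residual_sd and
            # tilt the slope
            mad_sd = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
            if mad_sd > 0:
                keep = np.abs(resid) <= 4.0 * mad_sd
                if keep.sum() >= min_obs and keep.sum() < keep.size:
                    x, y = x[keep], y[keep]
                    slope, intercept = np.polyfit(x, y, 1)
                    resid = y - (slope * x + intercept)
            residual_sd = float(np.std(resid, ddof=2))
            models.append(CorrelationModel(target, ref, float(slope),
                                           float(intercept), residual_sd))
            fitted_any = True
        if pairs and not fitted_any:
            untrained.append(sdef.system_id)
    return ModelSet(models), untrained


def collect_training_observations(
    spectra,
    panel: MetabolitePanel,
    min_snr: float = 10.0,
) -> pd.DataFrame:
    """Bootstrap-phase observation harvest for model training.

    Each spectrum is calibrated and transformed; reference multiplets are
    assigned by J-pattern matching in their coarse windows, while
    correlation targets and cross-check partners are seeded from a narrow
    window around their nominal delta (``bootstrap_halfwidth``) under a
    strict s/n demand.  Spectra that fail calibration are skipped — the
    training pool only ever sees well-behaved spectra, mirroring curated
    cohort construction.
    """
    from .assign import match_multiplet  # local: avoids a module cycle
    from .calibrate import calibrate_to_glucose
    from .transform import estimate_noise, pick_peaks, smolesy_transform

    ref_ids = sorted({r for s in panel.systems for r in s.correlation_refs})
    target_ids = [s.system_id for s in panel.systems
                  if s.strategy == "correlation" or s.crosscheck is not None]
    rows = []
    for i, spectrum in enumerate(spectra):
        cal, calres = calibrate_to_glucose(spectrum)
        if not calres.success:
            continue
        sm = smolesy_transform(cal)
        sigma = estimate_noise(sm)
        sample = cal.sample_id or f"s{i}"
        for rid in ref_ids:
            sdef = panel.by_id[rid]
            peaks = pick_peaks(sm, sdef.window, sigma, min_snr)
            res = match_multiplet(peaks, sdef, sm.sf_mhz)
            if res.assigned:
                rows.append((sample, rid, res.centroid))
        for tid in target_ids:
            sdef = panel.by_id[tid]
            seed = (sdef.delta - sdef.bootstrap_halfwidth,
                    sdef.delta + sdef.bootstrap_halfwidth)
            peaks = pick_peaks(sm, seed, sigma, min_snr)
            if peaks:
                rows.append((sample, tid, peaks[0].ppm))
    return pd.DataFrame(rows, columns=["sample", "system_id", "delta"])


# ---------------------------------------------------------------------------
# flat-file model store
# ---------------------------------------------------------------------------

def save_models(models: ModelSet, path) -> None:
    df = pd.DataFrame(
        [(m.target, m.reference, m.slope, m.intercept, m.residual_sd)
         for m in models.all_models()],
        columns=["target", "reference", "slope", "intercept", "residual_sd"],
    ).sort_values(["target", "reference"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_models(path=None) -> ModelSet:
    """Load a model store; with no path, the shipped synthetic-cohort defaults."""
    if path is None:
        from importlib import resources
        with (resources.files("smolesy") / "data" /
              "models_default.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(Path(path), sep="\t")
    return ModelSet([
        CorrelationModel(r.target, r.reference, float(r.slope),
                         float(r.intercept), float(r.residual_sd))
        for r in df.itertuples()
    ])
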