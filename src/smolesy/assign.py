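"""Assignment engine: J-pattern matching, window refinement, cross-checks.

The assignment of a spin system is the selection of the set of picked
SMolESY peaks that realises its expected multiplet: adjacent components
J/SF apart (within a tolerance of max(0.3 Hz, 15% of J)), heights
consistent with the binomial pattern (1:1, 1:2:1, 1:3:3:1) within a factor
of two — SMolESY distorts component height ratios when component widths
differ, so the band is deliberately loose.  Singlets are assigned as the
tallest peak inside either a correlation-refined window or a fixed narrow
window; creatinine's two singlets must additionally satisfy the fitted
intramolecular CH3<->CH2 shift relation or the weaker of the two is
demoted.

Everything is deterministic: candidate sets are scored (normalised spacing
error + height-ratio error), ties broken by proximity to the window
centre, then by summed height.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .calibrate import CalibrationResult, calibrate_to_glucose
from .models import ModelSet
from .panel import MetabolitePanel, SpinSystemDef
from .transform import (
    DEFAULT_NOISE_REGION,
    DEFAULT_SMOOTHING_WINDOWS,
    NOMINAL_SMOLESY_LINEWIDTH,
    Peak,
    SmolesySpectrum,
    estimate_noise,
    moving_average,
    pick_peaks,
    smolesy_transform,
)

__all__ = [
    "AssignmentResult",
    "match_multiplet",
    "refine_window",
    "assign_singlet",
    "creatinine_crosscheck",
    "assign_panel",
    "PanelAssignment",
]

#: candidate peaks considered per window during combinatorial matching
_MAX_PEAKS = 12

#: weight of the height-ratio term in the multiplet mismatch score
RATIO_ERROR_WEIGHT = 0.25

#: weight of the summed-height deficit term: among J- and ratio-consistent
#: candidate sets, near-noise decoys (which can look perfectly regular)
#: must not outrank a many-fold taller genuine multiplet
HEIGHT_DEFICIT_WEIGHT = 0.3


@dataclass
class AssignmentResult:
    """Outcome of assigning one spin system in one spectrum."""

    system_id: str
    assigned: bool = False
    component_positions: tuple = ()
    component_heights: tuple = ()
    score: float = 0.0
    failure_reason: str = ""
    used_window: tuple = ()
    flags: set = field(default_factory=set)

    @property
    def centroid(self) -> float:
        if not self.component_positions:
            return float("nan")
        return float(np.mean(self.component_positions))

    @property
    def max_height(self) -> float:
        if not self.component_heights:
            return 0.0
        return float(max(self.component_heights))


def _j_tolerance_ppm(j_hz: float, sf_mhz: float) -> float:
    return max(0.3, 0.15 * j_hz) / sf_mhz


def match_multiplet(
    peaks: list[Peak],
    sdef: SpinSystemDef,
    sf_mhz: float,
) -> AssignmentResult:
    """Best J- and ratio-consistent component set among picked peaks."""
    n = sdef.n_components
    window_center = 0.5 * (sdef.window[0] + sdef.window[1])
    res = AssignmentResult(system_id=sdef.system_id, used_window=sdef.window)
    if len(peaks) < n:
        res.failure_reason = "no peaks" if not peaks else "no J-consistent set"
        return res
    if n == 1:
        top = peaks[0]
        res.assigned = True
        res.component_positions = (top.ppm,)
        res.component_heights = (top.height,)
        return res

    j_ppm = sdef.j_hz / sf_mhz
    tol = _j_tolerance_ppm(sdef.j_hz, sf_mhz)
    weights = np.array(sdef.weights)
    by_pos = sorted(peaks[:_MAX_PEAKS], key=lambda p: p.ppm)

    passing = []
    saw_spacing_ok = False
    for combo in itertools.combinations(by_pos, n):
        pos = np.array([p.ppm for p in combo])
        hts = np.array([p.height for p in combo])
        spacings = np.diff(pos)
        if np.any(np.abs(spacings - j_ppm) > tol):
            continue
        saw_spacing_ok = True
        r = hts / weights
        if r.max() / r.min() > 2.0:
            continue
        spacing_err = float(np.mean(np.abs(spacings - j_ppm)) / j_ppm)
        ratio_err = float(np.mean(np.abs(np.log2(r / np.median(r)))))
        passing.append((pos, hts, spacing_err, ratio_err))
    if not passing:
        res.failure_reason = (
            "ratio violation" if saw_spacing_ok else "no J-consistent set"
        )
        return res
    # J spacing is the hard physical constraint; SMolESY height ratios are
    # distorted by width differences and neighbour interference, so they
    # enter with reduced weight; the height-deficit term demotes regular-
    # looking near-noise decoy sets relative to the tallest candidate.
    tallest_sum = max(float(h.sum()) for _, h, _, _ in passing)
    best = None
    best_key = None
    for pos, hts, spacing_err, ratio_err in passing:
        deficit = 1.0 - float(hts.sum()) / tallest_sum
        score = (spacing_err + RATIO_ERROR_WEIGHT * ratio_err
                 + HEIGHT_DEFICIT_WEIGHT * deficit)
        centroid = float(pos.mean())
        key = (score, abs(centroid - window_center), -float(hts.sum()))
        if best_key is None or key < best_key:
            best_key = key
            best = (tuple(map(float, pos)), tuple(map(float, hts)), score)
    res.assigned = True
    res.component_positions, res.component_heights, res.score = best
    return res


def refine_window(
    sdef: SpinSystemDef,
    models: ModelSet,
    ref_deltas: dict[str, float],
    linewidth: float = NOMINAL_SMOLESY_LINEWIDTH,
) -> tuple[tuple[float, float], set]:
    """Correlation-narrowed window for a singlet, clipped to the coarse one.

    Falls back to the coarse window (flag ``unrefined``) when the model is
    untrained or no reference was assigned in this spectrum.
    """
    flags: set[str] = set()
    if not models.is_trained(sdef.system_id):
        return sdef.window, {"unrefined", "low_confidence"}
    pred = models.predict(sdef.system_id, ref_deltas)
    if pred is None:
        return sdef.window, {"unrefined"}
    center, hw = pred
    lo = max(center - hw, sdef.window[0])
    hi = min(center + hw, sdef.window[1])
    if lo >= hi:
        # prediction escaped the coarse window entirely
        return sdef.window, {"unrefined", "prediction_outside_window"}
    if (center - hw < sdef.window[0]) or (center + hw > sdef.window[1]):
        flags.add("clipped")
    return (lo, hi), flags


def assign_singlet(
    peaks: list[Peak],
    window: tuple[float, float],
    sdef: SpinSystemDef,
) -> AssignmentResult:
    """Tallest peak inside the (refined or narrow) window; none -> unassigned."""
    res = AssignmentResult(system_id=sdef.system_id, used_window=window)
    inside = [p for p in peaks if window[0] <= p.ppm <= window[1]]
    if not inside:
        res.failure_reason = "no peaks"
        return res
    top = max(inside, key=lambda p: (p.height, -p.ppm))
    res.assigned = True
    res.component_positions = (top.ppm,)
    res.component_heights = (top.height,)
    return res


def creatinine_crosscheck(
    result_a: AssignmentResult,
    result_b: AssignmentResult,
    model,
    tolerance: float = 3 * NOMINAL_SMOLESY_LINEWIDTH,
) -> tuple[AssignmentResult, AssignmentResult]:
    """Enforce the intramolecular shift relation between two spin systems.

    ``model`` maps delta(a) -> delta(b) (a fitted CorrelationModel).  If
    both systems are assigned but the relation fails by more than
    ``tolerance``, the lower-s/n assignment is demoted with reason
    "crosscheck failed".  A lone assignment is kept, flagged
    ``partial_evidence``.
    """
    if result_a.assigned and not result_b.assigned:
        result_a.flags.add("partial_evidence")
        return result_a, result_b
    if result_b.assigned and not result_a.assigned:
        result_b.flags.add("partial_evidence")
        return result_a, result_b
    if not (result_a.assigned and result_b.assigned):
        return result_a, result_b
    if model is None:
        result_a.flags.add("crosscheck_unavailable")
        result_b.flags.add("crosscheck_unavailable")
        return result_a, result_b
    predicted_b = model.predict(result_a.centroid)
    if abs(result_b.centroid - predicted_b) <= tolerance:
        return result_a, result_b
    weaker = result_a if result_a.max_height <= result_b.max_height else result_b
    weaker.assigned = False
    weaker.component_positions = ()
    weaker.component_heights = ()
    weaker.failure_reason = "crosscheck failed"
    weaker.flags.add("crosscheck_failed")
    return result_a, result_b


@dataclass
class PanelAssignment:
    """Full per-spectrum assignment output."""

    results: list[AssignmentResult]
    calibration: CalibrationResult
    smolesy: SmolesySpectrum
    noise_sigma: float

    def by_id(self, system_id: str) -> AssignmentResult:
        for r in self.results:
            if r.system_id == system_id:
                return r
        raise KeyError(system_id)


def assign_panel(
    spectrum,
    panel: MetabolitePanel,
    models: ModelSet | None = None,
    smoothing_windows=DEFAULT_SMOOTHING_WINDOWS,
    noise_region=DEFAULT_NOISE_REGION,
    min_snr: float = 5.0,
) -> PanelAssignment:
    """Run the full assignment pipeline on one spectrum.

    Order: glucose calibration -> SMolESY transform -> window smoothing ->
    pattern multiplets (references first) -> correlation singlets ->
    narrow-window singlets -> cross-checks.  Exactly one result per panel
    spin system; a calibration failure does not abort, it marks every
    result ``uncalibrated``.
    """
    models = models or ModelSet()
    cal, calres = calibrate_to_glucose(spectrum, noise_region=noise_region)
    sm = smolesy_transform(cal)
    if smoothing_windows:
        sm = moving_average(sm, smoothing_windows)
    sigma = estimate_noise(sm, noise_region)

    results: dict[str, AssignmentResult] = {}

    # pattern-strategy multiplets (includes the lactate/alanine references
    # and the glucose doublet, re-matched on the calibrated axis)
    for sdef in panel.systems:
        if sdef.strategy != "pattern":
            continue
        peaks = pick_peaks(sm, sdef.window, sigma, min_snr)
        results[sdef.system_id] = match_multiplet(peaks, sdef, sm.sf_mhz)

    ref_deltas = {
        sid: r.centroid for sid, r in results.items() if r.assigned
    }

    # correlation-narrowed singlets
    for sdef in panel.systems:
        if sdef.strategy != "correlation":
            continue
        window, flags = refine_window(sdef, models, ref_deltas)
        peaks = pick_peaks(sm, window, sigma, min_snr)
        res = assign_singlet(peaks, window, sdef)
        res.flags |= flags
        results[sdef.system_id] = res

    # fixed narrow windows
    for sdef in panel.systems:
        if sdef.strategy != "narrow_window":
            continue
        peaks = pick_peaks(sm, sdef.window, sigma, min_snr)
        results[sdef.system_id] = assign_singlet(peaks, sdef.window, sdef)

    # intramolecular cross-checks (each unordered pair handled once)
    done = set()
    for sdef in panel.systems:
        partner = sdef.crosscheck
        if partner is None or (partner, sdef.system_id) in done:
            continue
        done.add((sdef.system_id, partner))
        model = models.pair(partner, sdef.system_id)
        a, b = results[sdef.system_id], results[partner]
        creatinine_crosscheck(a, b, model)

    for sdef in panel.systems:
        res = results[sdef.system_id]
        if sm.smoothed_mask[sm.window_slice(*sdef.window)].any():
            res.flags.add("smoothed")
        if not calres.success:
            res.flags.add("uncalibrated")

    ordered = [results[s.system_id] for s in panel.systems]
    return PanelAssignment(ordered, calres, sm, sigma)
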