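"""Chemical-shift calibration against the glucose anomeric doublet.

Blood-product 1H NMR spectra are conventionally referenced to the alpha
glucose H1 doublet at 5.233 ppm (J ~ 3.8 Hz), which is always present in
serum/plasma and sits clear of the macromolecular envelope.  Calibration
here is a pure axis relabelling: locate the doublet on the SMolESY
representation, subtract (found centre - 5.233) from the ppm axis.  No
interpolation, so the operation is exact and lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .spectra import Spectrum1D
from .transform import (
    DEFAULT_NOISE_REGION,
    SmolesySpectrum,
    estimate_noise,
    pick_peaks,
    smolesy_transform,
)

__all__ = [
    "GLUCOSE_ANOMERIC_PPM",
    "GLUCOSE_J_HZ",
    "CalibrationResult",
    "find_glucose_doublet",
    "calibrate_to_glucose",
]

#: reference position of the alpha-glucose H1 doublet centre (ppm)
GLUCOSE_ANOMERIC_PPM = 5.233
#: literature 3J(H1,H2) of alpha glucose, with a generous matching tolerance
GLUCOSE_J_HZ = 3.8
GLUCOSE_J_TOL_HZ = 0.8
#: coarse search window for the doublet (ppm)
GLUCOSE_SEARCH_WINDOW = (5.15, 5.32)


@dataclass
class CalibrationResult:
    shift_applied: float = 0.0
    doublet_center: float = float("nan")
    component_positions: tuple = ()
    component_heights: tuple = ()
    success: bool = False
    reason: str = ""


def find_glucose_doublet(
    sm: SmolesySpectrum,
    noise_sigma: float,
    search_window: tuple[float, float] = GLUCOSE_SEARCH_WINDOW,
    j_hz: float = GLUCOSE_J_HZ,
    j_tol_hz: float = GLUCOSE_J_TOL_HZ,
    min_snr: float = 5.0,
):
    """Locate the anomeric doublet among picked peaks.

    Qualifying pair: component separation within ``j_tol_hz`` of
    ``j_hz``/SF and heights within a factor of two of each other.  Among
    qualifying pairs the one with the highest summed height wins.

    Returns ``(center_ppm, (low_ppm, high_ppm), (h_low, h_high))`` or
    ``None`` when no pair qualifies.
    """
    peaks = pick_peaks(sm, search_window, noise_sigma, min_snr)
    j_ppm = j_hz / sm.sf_mhz
    tol_ppm = j_tol_hz / sm.sf_mhz
    best = None
    best_key = None
    for i in range(len(peaks)):
        for k in range(i + 1, len(peaks)):
            p, q = peaks[i], peaks[k]
            sep = abs(p.ppm - q.ppm)
            if abs(sep - j_ppm) > tol_ppm:
                continue
            ratio = p.height / q.height if q.height > 0 else float("inf")
            if not (0.5 <= ratio <= 2.0):
                continue
            key = (p.height + q.height, -abs(sep - j_ppm))
            if best_key is None or key > best_key:
                best_key = key
                lo, hi = sorted((p, q), key=lambda t: t.ppm)
                best = (
                    0.5 * (lo.ppm + hi.ppm),
                    (lo.ppm, hi.ppm),
                    (lo.height, hi.height),
                )
    return best


def calibrate_to_glucose(
    spectrum: Spectrum1D,
    noise_region: tuple[float, float] = DEFAULT_NOISE_REGION,
    reference_ppm: float = GLUCOSE_ANOMERIC_PPM,
) -> tuple[Spectrum1D, CalibrationResult]:
    """Shift the ppm axis so the glucose anomeric doublet sits at 5.233 ppm.

    On failure the spectrum is returned unchanged with a failure result;
    downstream assignment is expected to mark its outputs "uncalibrated".
    """
    sm = smolesy_transform(spectrum)
    try:
        sigma = estimate_noise(sm, noise_region)
    except ValueError:
        sigma = 0.0
    found = find_glucose_doublet(sm, sigma)
    if found is None:
        return spectrum, CalibrationResult(
            success=False,
            reason="no J- and height-consistent doublet in the glucose "
            "search window",
        )
    center, comps, heights = found
    shift = center - reference_ppm
    out = spectrum.shifted(shift)
    return out, CalibrationResult(
        shift_applied=shift,
        doublet_center=center - shift,
        component_positions=(comps[0] - shift, comps[1] - shift),
        component_heights=heights,
        success=True,
    )
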