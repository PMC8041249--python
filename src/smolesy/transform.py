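"""Small-molecule enhancement transform and basic signal utilities.

The transform (SMolESY) is the magnitude of the first derivative of the
dispersion channel with respect to chemical shift,

    S(delta) = | d Im(s) / d delta |.

For a Lorentzian line of half-width gamma the dispersion derivative peaks
at 1/(pi * gamma**2), so a line's SMolESY height scales with the *square*
of its sharpness: a 100 Hz macromolecular resonance is suppressed 10^4-fold
relative to a 1 Hz small-molecule line of the same area, while the
small-molecule line's apparent width shrinks to ~0.486 of the absorption
width.  That is the entire trick — no baseline model, no deconvolution.

This module also provides the 11-point moving-average denoiser applied in
designated noisy windows (aromatic region, near the water suppression
band), a robust noise estimator, and sub-grid peak picking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .spectra import Spectrum1D

__all__ = [
    "SmolesySpectrum",
    "Peak",
    "smolesy_transform",
    "moving_average",
    "estimate_noise",
    "pick_peaks",
    "DEFAULT_SMOOTHING_WINDOWS",
    "DEFAULT_NOISE_REGION",
    "NOMINAL_SMOLESY_LINEWIDTH",
]

#: windows (ppm) smoothed by default: aromatic region and near-water band.
DEFAULT_SMOOTHING_WINDOWS: tuple[tuple[float, float], ...] = (
    (6.5, 8.7),
    (4.3, 5.1),
)

#: default signal-free region of serum/plasma spectra used for the noise floor.
DEFAULT_NOISE_REGION: tuple[float, float] = (9.55, 9.95)

#: nominal SMolESY full width at half maximum at 600 MHz (ppm); the
#: instrument-class figure used to size assignment and integration windows.
NOMINAL_SMOLESY_LINEWIDTH = 0.0011

#: side-lobe rejection: |d(dispersion)/d(ppm)| of a Lorentzian has secondary
#: maxima of 12.5% of the main lobe at +/- sqrt(3)*gamma from the line
#: centre.  A picked peak this close to a much taller one is treated as the
#: tall peak's side lobe, not a resonance.
SIDELOBE_OFFSET_PPM = (0.0015, 0.0045)
SIDELOBE_HEIGHT_RATIO = 4.0


@dataclass
class SmolesySpectrum:
    """Nonnegative SMolESY intensity on the axis of its source spectrum."""

    ppm: np.ndarray
    intensity: np.ndarray
    sf_mhz: float
    smoothed_mask: np.ndarray = None
    source_id: str = ""
    flags: set = field(default_factory=set)

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.smoothed_mask is None:
            self.smoothed_mask = np.zeros(self.ppm.size, dtype=bool)
        if self.ppm.size != self.intensity.size:
            raise ValueError("ppm and intensity lengths differ")
        if np.any(self.intensity < 0):
            raise ValueError("SMolESY intensity must be nonnegative")

    @property
    def step(self) -> float:
        return float(abs(self.ppm[0] - self.ppm[-1]) / (self.ppm.size - 1))

    def window_slice(self, lo: float, hi: float) -> slice:
        return Spectrum1D.window_slice(self, lo, hi)

    def copy(self) -> "SmolesySpectrum":
        return SmolesySpectrum(
            ppm=self.ppm.copy(),
            intensity=self.intensity.copy(),
            sf_mhz=self.sf_mhz,
            smoothed_mask=self.smoothed_mask.copy(),
            source_id=self.source_id,
            flags=set(self.flags),
        )

    def to_spectrum(self) -> Spectrum1D:
        """Wrap as a Spectrum1D (imag zeroed) for tabular export."""
        return Spectrum1D(
            ppm=self.ppm.copy(),
            real=self.intensity.copy(),
            imag=np.zeros_like(self.intensity),
            sf_mhz=self.sf_mhz,
            sample_id=self.source_id,
            meta={"smolesy": "1"},
        )


class Peak(NamedTuple):
    ppm: float
    height: float


def smolesy_transform(spectrum: Spectrum1D) -> SmolesySpectrum:
    """Magnitude of the dispersion derivative w.r.t. chemical shift.

    Central differences on the uniform grid, one-sided at the two edges
    (``numpy.gradient``).  A spectrum whose dispersion channel is all zero
    while the absorption channel is not (magnitude-mode input, most likely)
    is transformed anyway but flagged ``"no_dispersion"``.
    """
    flags: set[str] = set()
    if not np.any(spectrum.imag) and np.any(spectrum.real):
        flags.add("no_dispersion")
    intensity = np.abs(np.gradient(spectrum.imag, spectrum.ppm))
    return SmolesySpectrum(
        ppm=spectrum.ppm.copy(),
        intensity=intensity,
        sf_mhz=spectrum.sf_mhz,
        source_id=spectrum.sample_id,
        flags=flags,
    )


def moving_average(
    sm: SmolesySpectrum,
    windows: Sequence[tuple[float, float]] = DEFAULT_SMOOTHING_WINDOWS,
    span: int = 11,
) -> SmolesySpectrum:
    """Centered unweighted moving average inside the given ppm windows.

    ``span`` must be odd (default 11).  Near a window boundary the kernel
    shrinks symmetrically so the output stays centered and the first/last
    points of the window are left at their own value.
    """
    if span % 2 == 0 or span < 3:
        raise ValueError(f"span must be an odd integer >= 3, got {span}")
    half = span // 2
    out = sm.copy()
    for lo, hi in windows:
        sl = sm.window_slice(lo, hi)
        seg = sm.intensity[sl]
        n = seg.size
        if n == 0:
            continue
        c = np.concatenate(([0.0], np.cumsum(seg)))
        i = np.arange(n)
        k = np.minimum(half, np.minimum(i, n - 1 - i))
        out.intensity[sl] = (c[i + k + 1] - c[i - k]) / (2 * k + 1)
        out.smoothed_mask[sl] = True
    return out


#: MAD of the half-normal distribution in units of the underlying normal
#: sigma; SMolESY intensities are |derivative|, i.e. folded noise, so the
#: usual 1.4826*MAD rule is rescaled by 1.4826 * 0.39894 to stay consistent
#: with the sigma of the signed derivative noise.
_HALF_NORMAL_MAD = 0.39894


def estimate_noise(
    sm: SmolesySpectrum,
    region: tuple[float, float] = DEFAULT_NOISE_REGION,
) -> float:
    """Robust noise sigma of the derivative noise in a signal-free region.

    MAD-based (breakdown point 50%), rescaled for the folding introduced
    by the magnitude: for white noise of sd ``s`` on the dispersion
    channel the returned sigma is ``s * sqrt(2) / (2h)`` with ``h`` the
    grid step — the sd of the signed central difference.
    """
    sl = sm.window_slice(*region)
    seg = sm.intensity[sl]
    if seg.size == 0:
        raise ValueError(
            f"noise region {region} lies outside the spectrum axis "
            f"[{sm.ppm[-1]:.3f}, {sm.ppm[0]:.3f}]"
        )
    if seg.size < 100:
        raise ValueError(
            f"noise region {region} contains only {seg.size} points (need >=100)"
        )
    med = np.median(seg)
    return float(np.median(np.abs(seg - med)) / _HALF_NORMAL_MAD)


def pick_peaks(
    sm: SmolesySpectrum,
    window: tuple[float, float],
    noise_sigma: float = 0.0,
    min_snr: float = 5.0,
    reject_sidelobes: bool = True,
) -> list[Peak]:
    """Local maxima in a ppm window, parabolic sub-grid position refinement.

    A point is a peak when strictly greater than both neighbours and at
    least ``min_snr * noise_sigma`` high.  With ``reject_sidelobes`` (the
    default) a peak is discarded when a >= 4x taller peak sits within the
    characteristic derivative side-lobe offset band (0.0015-0.0045 ppm) —
    taller candidates are searched slightly beyond the window edges so the
    filter does not depend on window placement.  Returned sorted by
    descending height.  An empty list is a valid result.
    """
    lo, hi = (window[1], window[0]) if window[0] > window[1] else window
    pad = SIDELOBE_OFFSET_PPM[1] if reject_sidelobes else 0.0
    sl = sm.window_slice(lo - pad, hi + pad)
    # one guard point each side so peaks at the window edge keep neighbours
    a = max(sl.start - 1, 0)
    b = min(sl.stop + 1, sm.ppm.size)
    seg = sm.intensity[a:b]
    if seg.size < 3:
        return []
    y0, y1, y2 = seg[:-2], seg[1:-1], seg[2:]
    is_max = (y1 > y0) & (y1 > y2) & (y1 >= min_snr * noise_sigma)
    idx = np.nonzero(is_max)[0] + 1  # index into seg
    candidates = []
    for i in idx:
        ym, yc, yp = seg[i - 1], seg[i], seg[i + 1]
        denom = ym - 2 * yc + yp
        frac = 0.5 * (ym - yp) / denom if denom != 0 else 0.0
        # frac is in grid-index units; axis decreases with index
        pos = float(sm.ppm[a + i] - frac * sm.step)
        height = float(yc - 0.25 * (ym - yp) * frac)
        candidates.append(Peak(pos, height))
    peaks = []
    for p in candidates:
        if not (lo <= p.ppm <= hi):
            continue
        if reject_sidelobes and any(
            q.height >= SIDELOBE_HEIGHT_RATIO * p.height
            and SIDELOBE_OFFSET_PPM[0]
            <= abs(q.ppm - p.ppm)
            <= SIDELOBE_OFFSET_PPM[1]
            for q in candidates
        ):
            continue
        peaks.append(p)
    peaks.sort(key=lambda p: (-p.height, p.ppm))
    return peaks
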