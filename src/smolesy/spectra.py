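"""Spectrum container and I/O for phased 1D NMR data.

The package works on frequency-domain spectra that keep *both* channels of
the phased signal: the absorption mode (``real``) and the dispersion mode
(``imag``).  The dispersion channel is not optional decoration — the
small-molecule enhancement transform differentiates it, so readers refuse
inputs that lack it.

Two dialects are supported:

* the Bruker processed-1D directory subset (``1r``, ``1i``, ``procs``), the
  form in which routine clinical/phenomic spectra are stored, and
* a plain tab-delimited text format (``# sf_mhz=...`` header, then
  ``ppm  real  imag`` columns) used for fixtures, exports and QC overlays.

Internally the ppm axis is always uniform and strictly decreasing (the NMR
display convention, high field to the right); ascending inputs are reversed
on read so downstream code never has to reason about axis direction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum1D",
    "read_bruker_1d",
    "read_tabular",
    "write_tabular",
    "write_bruker_1d",
]

#: relative tolerance (fraction of the spanned ppm range) for grid uniformity
GRID_RTOL = 1e-9


class SpectrumFormatError(ValueError):
    """Raised when an on-disk spectrum violates the dialect contract."""


@dataclass
class Spectrum1D:
    """A phased, frequency-domain 1D NMR spectrum on a uniform ppm grid.

    Parameters
    ----------
    ppm:
        Chemical-shift axis in ppm, uniformly spaced and strictly
        decreasing.
    real, imag:
        Absorption- and dispersion-mode intensities (arbitrary units).
    sf_mhz:
        Spectrometer (observe) frequency in MHz; converts Hz to ppm.
    sample_id:
        Opaque identifier carried through to result tables.
    meta:
        Free-form string metadata.
    """

    ppm: np.ndarray
    real: np.ndarray
    imag: np.ndarray
    sf_mhz: float
    sample_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.real = np.asarray(self.real, dtype=float)
        self.imag = np.asarray(self.imag, dtype=float)
        n = self.ppm.size
        if not (n == self.real.size == self.imag.size):
            raise ValueError(
                f"channel lengths differ: ppm={n}, real={self.real.size}, "
                f"imag={self.imag.size}"
            )
        # 3 points is the floor for central differences; realistic spectra
        # have tens of thousands of points and readers do not subdivide.
        if n < 3:
            raise ValueError(f"spectrum too short ({n} points, need >= 3)")
        if self.sf_mhz <= 0:
            raise ValueError(f"sf_mhz must be positive, got {self.sf_mhz}")
        d = np.diff(self.ppm)
        if np.any(d >= 0):
            raise ValueError("ppm axis must be strictly decreasing")
        _check_uniform(self.ppm)

    # -- convenience ------------------------------------------------------

    @property
    def step(self) -> float:
        """Grid step in ppm (positive)."""
        return float(abs(self.ppm[0] - self.ppm[-1]) / (self.ppm.size - 1))

    def window_slice(self, lo: float, hi: float) -> slice:
        """Index slice covering ppm interval [lo, hi] on the decreasing axis."""
        if lo > hi:
            lo, hi = hi, lo
        # decreasing axis: hi comes first
        idx = np.nonzero((self.ppm >= lo) & (self.ppm <= hi))[0]
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def shifted(self, delta_ppm: float) -> "Spectrum1D":
        """Return a copy with the ppm axis relabelled by ``-delta_ppm``.

        Pure relabelling — intensities are untouched, no interpolation.
        """
        return Spectrum1D(
            ppm=self.ppm - delta_ppm,
            real=self.real.copy(),
            imag=self.imag.copy(),
            sf_mhz=self.sf_mhz,
            sample_id=self.sample_id,
            meta=dict(self.meta),
        )

    def copy(self) -> "Spectrum1D":
        return self.shifted(0.0)


def _check_uniform(ppm: np.ndarray) -> None:
    d = np.diff(ppm)
    span = abs(ppm[0] - ppm[-1])
    dev = float(np.max(np.abs(d - d.mean())))
    tol = max(GRID_RTOL * span, 1e-12)
    if dev > tol:
        raise SpectrumFormatError(
            f"ppm grid is not uniform: max step deviation {dev:.3e} ppm "
            f"exceeds tolerance {tol:.3e} ppm"
        )


def _normalize_direction(ppm, real, imag):
    if ppm[0] < ppm[-1]:  # ascending input: flip to display convention
        return ppm[::-1].copy(), real[::-1].copy(), imag[::-1].copy()
    return ppm, real, imag


# ---------------------------------------------------------------------------
# Bruker processed-1D dialect
# ---------------------------------------------------------------------------

_PROCS_KEYS = ("SF", "OFFSET", "SW_p", "SI")


def _parse_procs(path: Path) -> dict:
    """Parse the JCAMP-like ``##$KEY= value`` lines of a procs file."""
    params: dict[str, float] = {}
    pat = re.compile(r"^##\$(\w+)=\s*(\S+)")
    for line in path.read_text().splitlines():
        m = pat.match(line.strip())
        if m:
            key, val = m.group(1), m.group(2)
            try:
                params[key] = float(val)
            except ValueError:
                pass
    return params


def read_bruker_1d(path) -> Spectrum1D:
    """Read a Bruker processed-data directory (``1r``, ``1i``, ``procs``).

    The ppm axis is reconstructed from the processing parameters as
    ``ppm[i] = OFFSET - i * (SW_p / SF) / SI`` and intensities are rescaled
    by ``2**NC_proc`` when the scaling exponent is present.  Only the
    phased, processed subset of the format is handled; FIDs, apodization
    and phase correction are upstream concerns.
    """
    d = Path(path)
    procs = d / "procs"
    if not procs.is_file():
        raise SpectrumFormatError(f"missing parameter file: {procs}")
    params = _parse_procs(procs)
    missing = [k for k in _PROCS_KEYS if k not in params]
    if missing:
        raise SpectrumFormatError(f"procs lacks required keys: {missing}")
    si = int(params["SI"])
    byte_order = ">" if int(params.get("BYTORDP", 0)) == 1 else "<"
    dtype = np.dtype(f"{byte_order}f8" if int(params.get("DTYPP", 0)) == 2
                     else f"{byte_order}i4")

    fr = d / "1r"
    fi = d / "1i"
    if not fr.is_file():
        raise SpectrumFormatError(f"missing real part file: {fr}")
    if not fi.is_file():
        raise SpectrumFormatError(
            f"missing imaginary part file: {fi} — the dispersion channel is "
            "required by the derivative transform"
        )
    real = np.fromfile(fr, dtype=dtype).astype(float)
    imag = np.fromfile(fi, dtype=dtype).astype(float)
    if real.size != si or imag.size != si:
        raise SpectrumFormatError(
            f"SI mismatch: procs says {si} points, 1r has {real.size}, "
            f"1i has {imag.size}"
        )
    scale = 2.0 ** params.get("NC_proc", 0.0)
    sw_ppm = params["SW_p"] / params["SF"]
    ppm = params["OFFSET"] - np.arange(si) * (sw_ppm / si)
    return Spectrum1D(
        ppm=ppm,
        real=real * scale,
        imag=imag * scale,
        sf_mhz=params["SF"],
        sample_id=d.name if d.name != "1" else d.parent.parent.name,
        meta={"dialect": "bruker"},
    )


def write_bruker_1d(spectrum: Spectrum1D, path) -> None:
    """Write a minimal Bruker-dialect directory (int32 ``1r``/``1i`` + procs).

    Intended for fixtures and round-trip tests.  Chooses the smallest
    ``NC_proc`` such that the scaled intensities fit in int32.
    """
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    si = spectrum.ppm.size
    peak = max(float(np.abs(spectrum.real).max()),
               float(np.abs(spectrum.imag).max()), 1e-300)
    # scale so the data nearly fill int32 (matches Bruker practice)
    nc = int(np.ceil(np.log2(peak / 2**30)))
    scale = 2.0 ** nc
    (d / "1r").write_bytes(
        np.round(spectrum.real / scale).astype("<i4").tobytes())
    (d / "1i").write_bytes(
        np.round(spectrum.imag / scale).astype("<i4").tobytes())
    sw_p = (spectrum.ppm[0] - spectrum.ppm[-1]) * si / (si - 1) * spectrum.sf_mhz
    lines = [
        "##TITLE= Parameter file, smolesy fixture writer",
        f"##$BYTORDP= 0",
        f"##$DTYPP= 0",
        f"##$NC_proc= {nc}",
        f"##$OFFSET= {float(spectrum.ppm[0])!r}",
        f"##$SF= {float(spectrum.sf_mhz)!r}",
        f"##$SI= {si}",
        f"##$SW_p= {float(sw_p)!r}",
        "##END=",
    ]
    (d / "procs").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

def write_tabular(spectrum: Spectrum1D, path, smolesy: bool = False) -> None:
    """Write the tab-delimited dialect at full floating precision."""
    p = Path(path)
    header = [f"# sf_mhz={spectrum.sf_mhz!r}"]
    if spectrum.sample_id:
        header.append(f"# sample_id={spectrum.sample_id}")
    if smolesy:
        header.append("# smolesy=1")
    header.append("ppm\treal\timag")
    body = "\n".join(
        f"{float(a)!r}\t{float(b)!r}\t{float(c)!r}"
        for a, b, c in zip(spectrum.ppm, spectrum.real, spectrum.imag)
    )
    p.write_text("\n".join(header) + "\n" + body + "\n")


def read_tabular(path) -> Spectrum1D:
    """Read the tab-delimited dialect written by :func:`write_tabular`."""
    p = Path(path)
    sf = None
    sample_id = ""
    meta = {"dialect": "tabular"}
    rows = []
    with p.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(\w+)\s*=\s*(\S+)", line)
                if m:
                    key, val = m.group(1), m.group(2)
                    if key == "sf_mhz":
                        sf = float(val)
                    elif key == "sample_id":
                        sample_id = val
                    else:
                        meta[key] = val
                continue
            if line.startswith("ppm"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise SpectrumFormatError(
                    f"{p}: expected 3 tab-separated columns, got {len(parts)}"
                )
            rows.append([float(x) for x in parts])
    if sf is None:
        raise SpectrumFormatError(f"{p}: missing '# sf_mhz=' header line")
    arr = np.array(rows, dtype=float)
    ppm, real, imag = _normalize_direction(arr[:, 0], arr[:, 1], arr[:, 2])
    _check_uniform(ppm)
    return Spectrum1D(ppm=ppm, real=real, imag=imag, sf_mhz=sf,
                      sample_id=sample_id or p.stem, meta=meta)
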