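"""Spectrum data model, text I/O and grid manipulation.

Wavenumbers are kept strictly ascending everywhere; files written in
descending instrument order are canonicalized on read. Resampling is by
linear interpolation onto a uniform grid (default 1 cm^-1), which keeps
"nearest cm^-1" band reporting well defined downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "Spectrum",
    "SpectralRegion",
    "FINGERPRINT",
    "OH_STRETCH",
    "SpectrumFormatError",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_spectrum_jcampdx",
    "resample",
    "extract_region",
]


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file cannot be parsed."""


@dataclass(frozen=True)
class SpectralRegion:
    """Closed wavenumber interval [lo, hi] in cm^-1."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"region requires lo < hi, got ({self.lo}, {self.hi})")

    def contains(self, wavenumbers: np.ndarray) -> np.ndarray:
        return (wavenumbers >= self.lo) & (wavenumbers <= self.hi)


#: Fingerprint region rich in nucleic-acid and carbohydrate bands.
FINGERPRINT = SpectralRegion(900.0, 1500.0)
#: Broad OH-stretch region reporting matrix hydrogen bonding.
OH_STRETCH = SpectralRegion(3000.0, 3700.0)


@dataclass
class Spectrum:
    """An absorbance spectrum on a strictly ascending wavenumber grid.

    Parameters
    ----------
    wavenumbers
        Strictly increasing array, cm^-1. Spacing may be non-uniform
        until :func:`resample` is applied.
    absorbance
        Same length as ``wavenumbers``; must be finite.
    meta
        Free-form metadata (sample id, temperature, formulation label...).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbance.ndim != 1:
            raise ValueError("wavenumbers and absorbance must be 1-D")
        if len(self.wavenumbers) != len(self.absorbance):
            raise ValueError(
                f"length mismatch: {len(self.wavenumbers)} wavenumbers vs "
                f"{len(self.absorbance)} absorbance values"
            )
        if len(self.wavenumbers) < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValueError("wavenumbers contain non-finite values")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    @property
    def support(self) -> SpectralRegion:
        return SpectralRegion(float(self.wavenumbers[0]), float(self.wavenumbers[-1]))

    def grid_step(self) -> float:
        """Uniform grid step, or raise if the grid is non-uniform."""
        d = np.diff(self.wavenumbers)
        if not np.allclose(d, d[0], rtol=1e-8, atol=1e-9):
            raise ValueError("grid is not uniform; resample first")
        return float(d[0])

    def copy_with(self, **meta) -> "Spectrum":
        m = dict(self.meta)
        m.update(meta)
        return Spectrum(self.wavenumbers.copy(), self.absorbance.copy(), m)


_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _is_number(token: str) -> bool:
    return bool(_NUMBER_RE.match(token.strip()))


def read_spectrum_csv(path, delimiter: str | None = None) -> Spectrum:
    """Read a two-column (wavenumber, absorbance) text spectrum.

    Comma- or whitespace-separated; an optional single header line is
    auto-detected by a non-numeric first token. Rows are canonicalized to
    ascending wavenumber order regardless of file order.
    """
    path = Path(path)
    wn: list[float] = []
    ab: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    first_data = True
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split(delimiter) if delimiter else line.replace(",", " ").split()
        tokens = [t for t in tokens if t]
        if first_data and tokens and not _is_number(tokens[0]):
            first_data = False  # header line, skip once
            continue
        first_data = False
        if len(tokens) < 2 or not (_is_number(tokens[0]) and _is_number(tokens[1])):
            raise SpectrumFormatError(
                f"{path}: cannot parse (wavenumber, absorbance) at line {lineno}: {raw!r}"
            )
        wn.append(float(tokens[0]))
        ab.append(float(tokens[1]))
    if len(wn) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 data rows")
    wn_arr = np.array(wn)
    ab_arr = np.array(ab)
    order = np.argsort(wn_arr, kind="stable")
    wn_arr, ab_arr = wn_arr[order], ab_arr[order]
    if np.any(np.diff(wn_arr) == 0):
        dup = wn_arr[np.flatnonzero(np.diff(wn_arr) == 0)[0]]
        raise SpectrumFormatError(f"{path}: duplicate wavenumber {dup}")
    return Spectrum(wn_arr, ab_arr, meta={"source": str(path)})


def write_spectrum_csv(path, s: Spectrum) -> None:
    """Write the canonical two-column CSV dialect (ascending, full precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("wavenumber,absorbance\n")
        for w, a in zip(s.wavenumbers, s.absorbance):
            fh.write(f"{float(w)!r},{float(a)!r}\n")


def _parse_jcamp_ldrs(text: str) -> dict[str, str]:
    ldrs: dict[str, str] = {}
    current = None
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            current = label.strip().upper().replace(" ", "").replace("-", "").replace("_", "")
            ldrs[current] = value.strip()
        elif current is not None and line.strip():
            ldrs[current] += "\n" + line
    return ldrs


def read_spectrum_jcampdx(path) -> Spectrum:
    """Read a JCAMP-DX 4.24 spectrum (AFFN ``XYDATA=(X++(Y..Y))`` or ``XYPOINTS``).

    SQZ/DIF/DUP compressed ordinates are out of scope and rejected.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        ldrs = _parse_jcamp_ldrs(fh.read())

    def fget(name: str, default: float | None = None) -> float | None:
        if name in ldrs:
            return float(ldrs[name].splitlines()[0])
        return default

    if "XYDATA" in ldrs:
        body = "\n".join(ldrs["XYDATA"].splitlines()[1:])
        if re.search(r"[A-DF-Za-df-z@%]", body):
            raise SpectrumFormatError(
                f"{path}: SQZ/DIF/DUP-compressed XYDATA is not supported (AFFN only)"
            )
        missing = [k for k in ("FIRSTX", "DELTAX") if k not in ldrs]
        if missing:
            raise SpectrumFormatError(f"{path}: missing required LDRs: {', '.join(missing)}")
        firstx = fget("FIRSTX")
        deltax = fget("DELTAX")
        if deltax == 0:
            raise SpectrumFormatError(f"{path}: DELTAX must be non-zero")
        xfactor = fget("XFACTOR", 1.0)
        yfactor = fget("YFACTOR", 1.0)
        wn: list[float] = []
        ab: list[float] = []
        for line in body.splitlines():
            vals = [float(t) for t in line.replace(",", " ").split()]
            if len(vals) < 2:
                continue
            x0 = vals[0]
            for j, y in enumerate(vals[1:]):
                wn.append((x0 + j * deltax) * xfactor)
                ab.append(y * yfactor)
    elif "XYPOINTS" in ldrs:
        body = "\n".join(ldrs["XYPOINTS"].splitlines()[1:])
        xfactor = fget("XFACTOR", 1.0)
        yfactor = fget("YFACTOR", 1.0)
        pairs = [p for p in re.split(r"[;\n]", body) if p.strip()]
        wn, ab = [], []
        for p in pairs:
            x, y = [float(t) for t in p.replace(",", " ").split()[:2]]
            wn.append(x * xfactor)
            ab.append(y * yfactor)
    else:
        raise SpectrumFormatError(f"{path}: missing required LDRs: XYDATA or XYPOINTS")

    if len(wn) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 data points")
    wn_arr, ab_arr = np.array(wn), np.array(ab)
    order = np.argsort(wn_arr, kind="stable")
    return Spectrum(wn_arr[order], ab_arr[order], meta={"source": str(path)})


def resample(s: Spectrum, grid_step: float = 1.0, region: SpectralRegion | None = None) -> Spectrum:
    """Linearly interpolate onto a uniform grid over *region* (endpoints included).

    No extrapolation: the region must lie within the spectrum's support.
    """
    if region is None:
        region = s.support
    lo, hi = float(s.wavenumbers[0]), float(s.wavenumbers[-1])
    if region.lo < lo - 1e-9 or region.hi > hi + 1e-9:
        raise ValueError(
            f"region ({region.lo}, {region.hi}) outside support ({lo}, {hi}); "
            "refusing to extrapolate"
        )
    n = int(round((region.hi - region.lo) / grid_step))
    grid = region.lo + grid_step * np.arange(n + 1)
    grid = grid[grid <= region.hi + 1e-9]
    ab = np.interp(grid, s.wavenumbers, s.absorbance)
    return Spectrum(grid, ab, meta=dict(s.meta))


def extract_region(s: Spectrum, region: SpectralRegion) -> Spectrum:
    """Sub-spectrum with all points lo <= nu <= hi; metadata preserved."""
    mask = region.contains(s.wavenumbers)
    if mask.sum() < 2:
        raise ValueError(
            f"region ({region.lo}, {region.hi}) has no overlap with support "
            f"({s.wavenumbers[0]}, {s.wavenumbers[-1]})"
        )
    return Spectrum(s.wavenumbers[mask], s.absorbance[mask], meta=dict(s.meta))
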