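"""Band detection, B/A marker extraction and the phosphate intensity ratio.

Bands appear as local minima of the second derivative. A detected minimum
must be negative — between overlapping gaussian bands the filter produces
shallow positive-valued dips (sidelobes) that are not absorbance bands, and
the sign test rejects them cleanly. Band intensity is |d2| at the minimum,
so ratios are positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from ftirdry.preprocess import DerivativeSpectrum
from ftirdry.spectral_core import FINGERPRINT, SpectralRegion

__all__ = [
    "Band",
    "MarkerSet",
    "RatioResult",
    "MARKER_WINDOWS",
    "detect_bands",
    "extract_markers",
    "phosphate_ratio",
    "classify_conformation",
    "marker_row",
]

#: Search windows bracketing both conformational endpoints of each marker.
MARKER_WINDOWS: dict[str, SpectralRegion] = {
    "cc": SpectralRegion(950.0, 985.0),
    "co": SpectralRegion(1040.0, 1065.0),
    "po2_sym": SpectralRegion(1075.0, 1100.0),
    "po2_asym": SpectralRegion(1200.0, 1260.0),
}

#: Marker endpoint positions: (A-form, B-form) in cm^-1.
_ENDPOINTS = {"cc": (965.0, 970.0), "co": (1050.0, 1052.0)}
# asym phosphate votes by threshold with an unassigned 1228-1230 gap
_ASYM_A_MIN = 1230.0
_ASYM_B_MAX = 1228.0

DEFAULT_MIN_PROMINENCE = 0.02


@dataclass(frozen=True)
class Band:
    position: float  # cm^-1, at a grid node
    intensity: float  # |d2| at the minimum
    prominence: float

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("band intensity must be > 0")


@dataclass
class MarkerSet:
    cc: Band | None = None
    co: Band | None = None
    po2_sym: Band | None = None
    po2_asym: Band | None = None
    state_assumed: str = "dried"

    def present(self) -> dict[str, Band]:
        return {
            k: v
            for k, v in (
                ("cc", self.cc),
                ("co", self.co),
                ("po2_sym", self.po2_sym),
                ("po2_asym", self.po2_asym),
            )
            if v is not None
        }


@dataclass(frozen=True)
class RatioResult:
    """I(PO2- asym) / I(PO2- sym) from second-derivative band intensities."""

    ratio: float
    asym_position_used: float
    sym_position_used: float


def detect_bands(
    d: DerivativeSpectrum,
    region: SpectralRegion,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> list[Band]:
    """Local negative minima of d2 in *region* with relative prominence
    >= min_prominence (a fraction of max |d2| over the region), sorted by
    position. Edge-invalidated points are excluded."""
    mask = region.contains(d.wavenumbers) & d.valid
    if mask.sum() < 3:
        raise ValueError(
            f"region ({region.lo}, {region.hi}) lies in the edge-invalid zone "
            "of the derivative"
        )
    w = d.wavenumbers[mask]
    y = d.d2[mask]
    scale = float(np.max(np.abs(y)))
    if scale == 0.0:
        return []
    idx, props = find_peaks(-y, prominence=min_prominence * scale)
    bands = []
    for i, prom in zip(idx, props["prominences"]):
        if y[i] >= 0:  # positive-valued dip: filter sidelobe, not a band
            continue
        bands.append(Band(position=round(float(w[i])), intensity=float(-y[i]),
                          prominence=float(prom)))
    return sorted(bands, key=lambda b: b.position)


def _best(bands: list[Band]) -> Band | None:
    """Most intense band; ties broken by prominence then lower wavenumber."""
    if not bands:
        return None
    return max(bands, key=lambda b: (b.intensity, b.prominence, -b.position))


def extract_markers(
    d: DerivativeSpectrum,
    state: str = "dried",
    windows: dict[str, SpectralRegion] = MARKER_WINDOWS,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> MarkerSet:
    """Pick per marker window the most intense detected band (or absent).

    The prominence threshold is referenced to max |d2| over the fingerprint
    region so all four windows share one scale.
    """
    if state not in ("hydrated", "dried"):
        raise ValueError("state must be 'hydrated' or 'dried'")
    vr = d.valid_region()
    search = SpectralRegion(max(940.0, vr.lo), min(1270.0, vr.hi))
    fp = SpectralRegion(max(FINGERPRINT.lo, vr.lo), min(FINGERPRINT.hi, vr.hi))
    fp_mask = fp.contains(d.wavenumbers) & d.valid
    scale = float(np.max(np.abs(d.d2[fp_mask])))
    # threshold against the fingerprint-wide scale so all windows share it
    all_bands = [
        b
        for b in detect_bands(d, search, min_prominence=0.0)
        if scale > 0 and b.prominence >= min_prominence * scale
    ]
    ms = MarkerSet(state_assumed=state)
    for name, win in windows.items():
        inside = [b for b in all_bands if win.lo <= b.position <= win.hi]
        setattr(ms, name, _best(inside))
    return ms


def phosphate_ratio(m: MarkerSet) -> RatioResult:
    """Asymmetric/symmetric phosphate second-derivative intensity ratio."""
    missing = [n for n in ("po2_sym", "po2_asym") if getattr(m, n) is None]
    if missing:
        raise ValueError(f"cannot form phosphate ratio: missing band(s) {missing}")
    return RatioResult(
        ratio=m.po2_asym.intensity / m.po2_sym.intensity,
        asym_position_used=m.po2_asym.position,
        sym_position_used=m.po2_sym.position,
    )


def classify_conformation(m: MarkerSet) -> str:
    """Majority vote of the cc/co/po2_asym markers: 'B', 'A_like' or
    'indeterminate'. Markers at their A-side endpoint vote A_like, at the
    B side vote B (nearest endpoint; the 1228-1230 asym gap abstains)."""
    votes: list[str] = []
    usable = 0
    for name, (a_pos, b_pos) in _ENDPOINTS.items():
        band = getattr(m, name)
        if band is None:
            continue
        usable += 1
        da, db = abs(band.position - a_pos), abs(band.position - b_pos)
        if da < db:
            votes.append("A_like")
        elif db < da:
            votes.append("B")
        # equidistant: abstain
    if m.po2_asym is not None:
        usable += 1
        if m.po2_asym.position >= _ASYM_A_MIN:
            votes.append("A_like")
        elif m.po2_asym.position <= _ASYM_B_MAX:
            votes.append("B")
    if usable < 2:
        return "indeterminate"
    n_a = votes.count("A_like")
    n_b = votes.count("B")
    if n_a > n_b:
        return "A_like"
    if n_b > n_a:
        return "B"
    return "indeterminate"


def marker_row(m: MarkerSet) -> dict:
    """Flatten a MarkerSet into one CSV-ready row."""
    row: dict = {"state_assumed": m.state_assumed}
    for name in ("cc", "co", "po2_sym", "po2_asym"):
        band = getattr(m, name)
        row[f"{name}_position"] = band.position if band else ""
        row[f"{name}_intensity"] = band.intensity if band else ""
    try:
        row["phosphate_ratio"] = phosphate_ratio(m).ratio
    except ValueError:
        row["phosphate_ratio"] = ""
    row["conformation"] = classify_conformation(m)
    return row
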