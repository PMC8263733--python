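"""OH-stretch band position (80%-height rule) and wavenumber temperature
coefficient (WTC) fitting.

The band position is the mean of the two wavenumbers where absorbance
crosses 80% of the full peak height inside 3000-3700 cm^-1; full height is
measured from zero absorbance (inputs assumed baseline-corrected). The WTC
is the ordinary least-squares slope of position on temperature over the
25-50 degC fit range; glassy matrices show small WTC, liquids large.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ftirdry.spectral_core import OH_STRETCH, SpectralRegion, Spectrum, extract_region

__all__ = ["VOHSeries", "WTCResult", "WTCComparison", "voh_position", "fit_wtc",
           "compare_wtc", "BandClippedError"]


class BandClippedError(ValueError):
    """The 80% level is not crossed on both flanks inside the region."""


@dataclass
class VOHSeries:
    temperatures: np.ndarray
    positions: np.ndarray
    sample_label: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.temperatures) != len(self.positions):
            raise ValueError("temperatures and positions must have equal length")
        if len(self.temperatures) < 2:
            raise ValueError("a series needs at least 2 points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(self.positions < 3000.0) or np.any(self.positions > 3700.0):
            raise ValueError("positions must lie within 3000-3700 cm^-1")


@dataclass(frozen=True)
class WTCResult:
    wtc: float  # cm^-1 per degC
    intercept: float  # cm^-1 at 0 degC
    fit_range: tuple[float, float]
    n_points: int
    residual_rms: float
    sample_label: str = ""


@dataclass(frozen=True)
class WTCComparison:
    larger: str  # 'a', 'b' or 'equal'
    difference: float  # a.wtc - b.wtc


def voh_position(
    s: Spectrum,
    region: SpectralRegion = OH_STRETCH,
    height_fraction: float = 0.8,
    subtract_linear_baseline: bool = False,
) -> float:
    """Mean of the two outermost crossings of the 80%-height level.

    Crossings are located by linear interpolation between bracketing grid
    points; outermost crossings make the rule robust to small shoulder dips
    near the peak. Raises :class:`BandClippedError` when a flank does not
    cross the level inside the region.
    """
    sub = extract_region(s, region)
    w, a = sub.wavenumbers, sub.absorbance.copy()
    if subtract_linear_baseline:
        base = a[0] + (a[-1] - a[0]) * (w - w[0]) / (w[-1] - w[0])
        a = a - base
    ipk = int(np.argmax(a))
    level = height_fraction * a[ipk]

    def cross(i: int, j: int) -> float:
        # linear interpolation of the level crossing between grid points i, j
        return w[i] + (level - a[i]) * (w[j] - w[i]) / (a[j] - a[i])

    left = None
    for i in range(ipk):  # outermost rising crossing on the left flank
        if a[i] < level <= a[i + 1]:
            left = cross(i, i + 1)
            break
    right = None
    for i in range(len(a) - 2, ipk - 1, -1):  # outermost falling crossing
        if a[i] >= level > a[i + 1]:
            right = cross(i, i + 1)
            break
    if left is None or right is None:
        flank = "left" if left is None else "right"
        raise BandClippedError(
            f"band clipped: {flank} flank does not cross the "
            f"{height_fraction:.0%} level inside ({region.lo}, {region.hi})"
        )
    return 0.5 * (left + right)


def voh_series(
    spectra: list[tuple[float, Spectrum]], sample_label: str = ""
) -> VOHSeries:
    """Build a VOHSeries from (temperature, spectrum) pairs (sorted by T)."""
    pairs = sorted(spectra, key=lambda p: p[0])
    temps = np.array([t for t, _ in pairs])
    pos = np.array([voh_position(s) for _, s in pairs])
    return VOHSeries(temps, pos, sample_label)


def fit_wtc(series: VOHSeries, fit_range: tuple[float, float] = (25.0, 50.0)) -> WTCResult:
    """OLS line of band position on temperature, endpoints inclusive."""
    lo, hi = fit_range
    mask = (series.temperatures >= lo) & (series.temperatures <= hi)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"need >= 3 points inside fit range {fit_range}, have {n}")
    t = series.temperatures[mask]
    p = series.positions[mask]
    slope, intercept = np.polyfit(t, p, 1)
    resid = p - (slope * t + intercept)
    return WTCResult(
        wtc=float(slope),
        intercept=float(intercept),
        fit_range=(float(lo), float(hi)),
        n_points=n,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        sample_label=series.sample_label,
    )


def compare_wtc(a: WTCResult, b: WTCResult) -> WTCComparison:
    """Which WTC is larger, and by how much (a minus b). No significance claim."""
    diff = a.wtc - b.wtc
    larger = "a" if diff > 0 else ("b" if diff < 0 else "equal")
    return WTCComparison(larger=larger, difference=diff)
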