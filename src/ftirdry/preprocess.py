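"""Vector normalization and Savitzky-Golay second differentiation.

The default processing chain mirrors common chemometric practice:
vector-normalize the absorbance over the region of interest, then take
the 21-point Savitzky-Golay second derivative. The derivative is scaled
by 1/h^2 so its units are per cm^2 and band-intensity ratios do not
depend on the grid step. The half-window at each edge is flagged invalid
rather than padded — padding fabricates curvature at region borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from ftirdry.spectral_core import SpectralRegion, Spectrum, extract_region

__all__ = ["DerivativeSpectrum", "vector_normalize", "second_derivative",
           "normalized_second_derivative"]


@dataclass
class DerivativeSpectrum:
    """Second derivative of absorbance on a uniform grid.

    ``valid`` masks out the half-window at each edge where the filter
    output is unreliable; downstream peak search must respect it.
    """

    wavenumbers: np.ndarray
    d2: np.ndarray
    valid: np.ndarray
    window_points: int
    poly_order: int
    normalized: bool = False

    def valid_region(self) -> SpectralRegion:
        w = self.wavenumbers[self.valid]
        return SpectralRegion(float(w[0]), float(w[-1]))


def vector_normalize(s: Spectrum, region: SpectralRegion | None = None) -> Spectrum:
    """Restrict to *region* and divide by the Euclidean norm over it."""
    sub = extract_region(s, region) if region is not None else s
    norm = float(np.linalg.norm(sub.absorbance))
    if norm == 0.0:
        raise ValueError("cannot vector-normalize: zero norm over region")
    out = sub.copy_with(normalized="vector")
    out.absorbance = sub.absorbance / norm
    return out


def second_derivative(
    s: Spectrum, window_points: int = 21, poly_order: int = 3
) -> DerivativeSpectrum:
    """Savitzky-Golay second derivative, reported per cm^2.

    Requires a uniform grid (resample first) at least window_points long.
    """
    if window_points % 2 != 1 or window_points < poly_order + 2:
        raise ValueError("window_points must be odd and >= poly_order + 2")
    h = s.grid_step()
    if len(s) < window_points:
        raise ValueError(
            f"spectrum has {len(s)} points, fewer than window_points={window_points}"
        )
    d2 = savgol_filter(s.absorbance, window_points, poly_order, deriv=2, delta=h)
    valid = np.ones(len(s), dtype=bool)
    half = window_points // 2
    valid[:half] = False
    valid[-half:] = False
    return DerivativeSpectrum(
        wavenumbers=s.wavenumbers.copy(),
        d2=d2,
        valid=valid,
        window_points=window_points,
        poly_order=poly_order,
        normalized=bool(s.meta.get("normalized")),
    )


def normalized_second_derivative(
    s: Spectrum,
    region: SpectralRegion,
    window_points: int = 21,
    poly_order: int = 3,
    normalize_after: bool = False,
) -> DerivativeSpectrum:
    """Vector-normalize over *region* then differentiate (the default order).

    With ``normalize_after`` the derivative itself is scaled to unit norm
    over its valid range instead — the alternative reading of
    "normalized second derivative".
    """
    if normalize_after:
        d = second_derivative(extract_region(s, region), window_points, poly_order)
        norm = float(np.linalg.norm(d.d2[d.valid]))
        if norm == 0.0:
            raise ValueError("cannot normalize: zero derivative norm")
        d.d2 = d.d2 / norm
        d.normalized = True
        return d
    return second_derivative(vector_normalize(s, region), window_points, poly_order)
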