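"""Non-spectral dry-preservation assays.

Gravimetric water content and drying endpoint, percent-w/v to molarity
conversion, and formazan grey-value quantification of micrographs, with
small synthetic generators for curves and images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DryingCurve",
    "GreyImage",
    "water_content",
    "drying_endpoint",
    "percent_wv_to_molar",
    "formazan_grey",
    "blank_subtract",
    "simulate_drying_curve",
    "simulate_formazan_disc",
    "grey_from_rgb",
]

#: Rec. 601 luma weights for converting RGB micrographs to greyscale.
_REC601 = np.array([0.299, 0.587, 0.114])


@dataclass
class DryingCurve:
    """Slide+sample weight versus drying time."""

    times: np.ndarray  # min, increasing
    weights: np.ndarray  # g, slide + sample
    slide_weight: float  # g

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.times) != len(self.weights):
            raise ValueError("times and weights must have equal length")
        if len(self.times) < 3:
            raise ValueError("a drying curve needs at least 3 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(self.weights > self.slide_weight):
            raise ValueError("all weights must exceed the slide weight")

    def net_weights(self) -> np.ndarray:
        return self.weights - self.slide_weight


@dataclass
class GreyImage:
    """8-bit greyscale micrograph; calibration maps grey to optical units."""

    pixels: np.ndarray
    calibration: tuple[float, float] = (1.0, 0.0)  # (gain, offset), identity default

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")


def grey_from_rgb(rgb: np.ndarray) -> GreyImage:
    """Convert an RGB array to 8-bit grey with Rec. 601 luma weights."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("expected an H x W x 3 RGB array")
    grey = rgb[..., :3] @ _REC601
    return GreyImage(np.clip(np.round(grey), 0, 255).astype(np.uint8))


def water_content(
    weight_after_drying: float, weight_after_bake: float, slide_weight: float
) -> float:
    """Residual water per gram dry weight from the bake-out weight loss.

    (after_drying - after_bake) / (after_bake - slide), g H2O per g dry.
    """
    if not weight_after_drying >= weight_after_bake > slide_weight:
        raise ValueError(
            "expected weight_after_drying >= weight_after_bake > slide_weight "
            "(evaporation cannot add mass)"
        )
    return (weight_after_drying - weight_after_bake) / (weight_after_bake - slide_weight)


def drying_endpoint(
    curve: DryingCurve, rel_tol: float = 0.005, window: int = 3
) -> float | None:
    """Earliest time at which the net weight is stable.

    Stable means: over `window` consecutive readings starting there, the
    relative spread (max-min)/first is below rel_tol. Returns None when no
    stable stretch exists ("not reached").
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    v = curve.net_weights()
    n = len(v)
    for i in range(n - window + 1):
        seg = v[i : i + window]
        if (seg.max() - seg.min()) / v[i] < rel_tol:
            return float(curve.times[i])
    return None


def percent_wv_to_molar(percent_wv: float, molar_mass: float) -> float:
    """Convert % w/v (g per 100 mL) to millimolar given molar mass g/mol."""
    if molar_mass <= 0:
        raise ValueError("molar_mass must be > 0")
    if percent_wv < 0:
        raise ValueError("percent_wv must be >= 0")
    return 10.0 * percent_wv / molar_mass * 1000.0


def formazan_grey(
    img: GreyImage, background_grey: float, mask: np.ndarray | None = None
) -> float:
    """Formazan index: background grey minus mean pixel grey, floored at 0.

    Darker (more formazan) specimens score higher; the inversion makes the
    index increase with coloration intensity.
    """
    px = img.pixels.astype(float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != px.shape:
            raise ValueError("mask shape must match image shape")
        if not mask.any():
            raise ValueError("empty mask")
        px = px[mask]
    return max(0.0, background_grey - float(px.mean()))


def blank_subtract(absorbance: float, blank: float) -> float:
    """Single-wavelength blank subtraction for colorimetric readouts."""
    return absorbance - blank


def simulate_drying_curve(
    tau: float,
    w_dry: float,
    w_water0: float,
    slide: float,
    step: float = 2.0,
    n: int = 20,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> DryingCurve:
    """Exponential water-loss curve: slide + w_dry + w_water0 * exp(-t/tau)."""
    if min(tau, w_dry, w_water0, step) <= 0 or n < 3:
        raise ValueError("tau, w_dry, w_water0, step must be positive and n >= 3")
    if noise_sd > 0 and seed is None:
        raise ValueError("seed required when noise_sd > 0")
    t = step * np.arange(n)
    w = slide + w_dry + w_water0 * np.exp(-t / tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        w = w + rng.normal(0.0, noise_sd, size=n)
        w = np.maximum(w, slide + 1e-12)  # keep curve physically valid
    return DryingCurve(t, w, slide)


def simulate_formazan_disc(
    shape: tuple[int, int],
    background: int,
    darkness: int,
    radius_fraction: float,
    center: tuple[float, float] | None = None,
) -> GreyImage:
    """Uniform background with a darker centered disc (a stained specimen)."""
    h, w = shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    r = radius_fraction * min(h, w) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    disc = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r * r
    px = np.full(shape, background, dtype=float)
    px[disc] -= darkness
    return GreyImage(np.clip(px, 0, 255).astype(np.uint8))
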