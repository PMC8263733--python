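"""Synthetic composite FTIR spectra with known band structure.

Component presets plant the diagnostic bands at their literature positions
(B-form dsDNA markers at 970/1052/1089/1225 cm^-1, A-form at
965/1050/1089/1235 cm^-1, ribose-ring RNA bands at 993/1125 cm^-1, five
dried-trehalose peaks in 960-1170 cm^-1, amide I/II for albumin). Band
widths are chosen so the composite's Savitzky-Golay second-derivative
minima fall within 1 cm^-1 of every planted center on a 1 cm^-1 grid —
that recovery is enforced by the test suite, not assumed.

Hydration morphs DNA marker centers linearly between the B (hydration=1)
and A (hydration=0) endpoints; the symmetric-phosphate amplitude grows by
a factor (1 + k*(1-hydration)) on drying. The broad OH-stretch band center
moves linearly with temperature at the preset's wavenumber temperature
coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ftirdry.spectral_core import SpectralRegion, Spectrum

__all__ = [
    "BandComponent",
    "VOHParams",
    "ComponentPreset",
    "FormulationSpec",
    "DegradationSpec",
    "PRESETS",
    "band_profile",
    "generate_component",
    "generate_formulation",
    "degrade",
    "dna_bands",
]

_FOUR_LN2 = 4.0 * math.log(2.0)

#: Default drying boost of the symmetric-phosphate amplitude (free parameter).
SYM_BOOST_K = 0.5


@dataclass(frozen=True)
class BandComponent:
    """One absorbance band: center/fwhm in cm^-1, unitless amplitude."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if not 650.0 <= self.center <= 4000.0:
            raise ValueError(f"center {self.center} outside 650-4000 cm^-1")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class VOHParams:
    """OH-stretch position model: center0 at 25 degC plus wtc per degC."""

    center0: float
    wtc: float


@dataclass(frozen=True)
class ComponentPreset:
    name: str
    bands: tuple[BandComponent, ...]
    voh_params: VOHParams | None = None

    def band_centers(self) -> list[float]:
        return [b.center for b in self.bands]


def _g(center: float, fwhm: float, amp: float) -> BandComponent:
    return BandComponent(center, fwhm, amp, "gaussian")


# Index order of the DNA marker bands inside the dsDNA presets:
# 0 = C-C backbone, 1 = C-O deoxyribose, 2 = PO2- sym, 3 = PO2- asym.
_DSDNA_B_BANDS = (
    _g(970.0, 16.0, 0.40),
    _g(1052.0, 16.0, 0.60),
    _g(1089.0, 18.0, 1.00),
    _g(1225.0, 22.0, 0.80),
)
_DSDNA_A_BANDS = (
    _g(965.0, 16.0, 0.40),
    _g(1050.0, 16.0, 0.60),
    _g(1089.0, 18.0, 1.00 * (1.0 + SYM_BOOST_K)),
    _g(1235.0, 22.0, 0.80),
)

PRESETS: dict[str, ComponentPreset] = {
    "dsDNA_B": ComponentPreset("dsDNA_B", _DSDNA_B_BANDS),
    "dsDNA_A": ComponentPreset("dsDNA_A", _DSDNA_A_BANDS),
    "ssDNA": ComponentPreset(
        "ssDNA",
        (
            _g(965.0, 18.0, 0.30),
            _g(1053.0, 18.0, 0.55),
            _g(1089.0, 20.0, 1.10),
            _g(1240.0, 26.0, 0.60),
        ),
    ),
    "RNA": ComponentPreset(
        "RNA",
        (
            _g(993.0, 16.0, 0.60),
            _g(1060.0, 18.0, 0.50),
            _g(1089.0, 18.0, 0.90),
            _g(1125.0, 16.0, 0.55),
            _g(1240.0, 22.0, 0.60),
        ),
    ),
    "trehalose_dry": ComponentPreset(
        "trehalose_dry",
        (
            _g(994.0, 16.0, 0.50),
            _g(1033.0, 16.0, 0.70),
            _g(1080.0, 16.0, 0.60),
            _g(1105.0, 16.0, 0.55),
            _g(1150.0, 16.0, 0.45),
            _g(3320.0, 300.0, 0.80),
        ),
        voh_params=VOHParams(3320.0, 0.1),
    ),
    "sucrose_dry": ComponentPreset(
        "sucrose_dry",
        (
            _g(990.0, 16.0, 0.55),
            _g(1055.0, 16.0, 0.65),
            _g(1120.0, 16.0, 0.50),
            _g(3315.0, 300.0, 0.80),
        ),
        voh_params=VOHParams(3315.0, 0.2),
    ),
    "albumin": ComponentPreset(
        "albumin",
        (
            _g(1395.0, 18.0, 0.35),
            _g(1455.0, 18.0, 0.40),
            _g(1550.0, 24.0, 0.85),
            _g(1650.0, 26.0, 1.00),
            _g(3290.0, 160.0, 0.60),
        ),
    ),
    "water_OH": ComponentPreset(
        "water_OH",
        (_g(3390.0, 300.0, 1.00),),
        voh_params=VOHParams(3390.0, 0.8),
    ),
    "trehalose_5pct": ComponentPreset(
        "trehalose_5pct",
        (_g(3380.0, 300.0, 0.95),),
        voh_params=VOHParams(3380.0, 0.7),
    ),
    "trehalose_40pct": ComponentPreset(
        "trehalose_40pct",
        (_g(3345.0, 300.0, 0.90),),
        voh_params=VOHParams(3345.0, 0.5),
    ),
    "matrix_OH_liquid": ComponentPreset(
        "matrix_OH_liquid",
        (_g(3360.0, 300.0, 0.90),),
        voh_params=VOHParams(3360.0, 0.6),
    ),
    "matrix_OH_glassy": ComponentPreset(
        "matrix_OH_glassy",
        (_g(3310.0, 310.0, 0.80),),
        voh_params=VOHParams(3310.0, 0.1),
    ),
}

#: Presets whose marker bands morph with hydration between the A/B endpoints.
_DNA_MORPH_PRESETS = frozenset({"dsDNA_A", "dsDNA_B", "dsDNA"})


@dataclass(frozen=True)
class FormulationSpec:
    """Recipe for one composite spectrum.

    hydration=1 means fully hydrated (B-form DNA markers), 0 means dried
    (A-form). A seed is mandatory whenever noise_sd > 0; there is no
    implicit global randomness.
    """

    components: dict[str, float]
    hydration: float = 1.0
    temperature: float = 25.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not any(w > 0 for w in self.components.values()):
            raise ValueError("at least one component weight must be positive")
        if any(w < 0 for w in self.components.values()):
            raise ValueError("component weights must be >= 0")
        unknown = set(self.components) - set(PRESETS) - {"dsDNA"}
        if unknown:
            raise ValueError(f"unknown presets: {sorted(unknown)}")
        if not 0.0 <= self.hydration <= 1.0:
            raise ValueError("hydration must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("seed is required when noise_sd > 0")


@dataclass(frozen=True)
class DegradationSpec:
    """Storage-degradation model: per-band amplitude rescale and center shift.

    severity=0 is the exact identity; drifts scale linearly with severity
    with a small seeded per-band jitter.
    """

    severity: float
    affected_bands: tuple[float, ...] = (1089.0, 1235.0)
    amplitude_drift: float = -0.3
    center_drift: float = 2.0
    seed: int = 0
    neighborhood_fwhm: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must be in [0, 1]")


def band_profile(b: BandComponent, grid: np.ndarray) -> np.ndarray:
    """Evaluate one band on a wavenumber grid (peak value = amplitude)."""
    grid = np.asarray(grid, dtype=float)
    x = grid - b.center
    if b.shape == "gaussian":
        return b.amplitude * np.exp(-_FOUR_LN2 * x * x / (b.fwhm * b.fwhm))
    return b.amplitude / (1.0 + 4.0 * x * x / (b.fwhm * b.fwhm))


def _make_grid(grid_step: float, region: SpectralRegion) -> np.ndarray:
    n = int(round((region.hi - region.lo) / grid_step))
    grid = region.lo + grid_step * np.arange(n + 1)
    return grid[grid <= region.hi + 1e-9]


def generate_component(
    preset: ComponentPreset | str,
    grid_step: float = 1.0,
    region: SpectralRegion = SpectralRegion(650.0, 4000.0),
) -> Spectrum:
    """Noise-free sum of one preset's bands on a uniform grid."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if region.lo < 650.0 or region.hi > 4000.0:
        raise ValueError("region must lie within 650-4000 cm^-1")
    grid = _make_grid(grid_step, region)
    ab = np.zeros_like(grid)
    meta = {"preset": preset.name}
    if not preset.bands:
        meta["empty_preset"] = True
    for b in preset.bands:
        ab += band_profile(b, grid)
    return Spectrum(grid, ab, meta=meta)


def dna_bands(hydration: float, base: str = "dsDNA_B") -> tuple[BandComponent, ...]:
    """DNA marker bands at the given hydration.

    Centers and amplitudes interpolate linearly between the B-form
    (hydration=1) and A-form (hydration=0) endpoint presets; at hydration 0
    the symmetric-phosphate amplitude carries the full drying boost.
    """
    h = float(hydration)
    out = []
    for bb, ba in zip(_DSDNA_B_BANDS, _DSDNA_A_BANDS):
        out.append(
            BandComponent(
                center=h * bb.center + (1 - h) * ba.center,
                fwhm=h * bb.fwhm + (1 - h) * ba.fwhm,
                amplitude=h * bb.amplitude + (1 - h) * ba.amplitude,
                shape=bb.shape,
            )
        )
    return tuple(out)


def _effective_bands(name: str, spec: FormulationSpec) -> tuple[BandComponent, ...]:
    if name in _DNA_MORPH_PRESETS:
        return dna_bands(spec.hydration)
    preset = PRESETS[name]
    if preset.voh_params is None:
        return preset.bands
    # shift the broad OH band with temperature at the preset's coefficient
    vp = preset.voh_params
    center_t = vp.center0 + vp.wtc * (spec.temperature - 25.0)
    bands = []
    for b in preset.bands:
        if b.fwhm >= 100.0 and b.center > 3000.0:  # the OH-stretch band
            bands.append(BandComponent(center_t, b.fwhm, b.amplitude, b.shape))
        else:
            bands.append(b)
    return tuple(bands)


def generate_formulation(
    spec: FormulationSpec,
    grid_step: float = 1.0,
    region: SpectralRegion = SpectralRegion(650.0, 4000.0),
) -> Spectrum:
    """Weighted composite of component spectra plus optional gaussian noise."""
    grid = _make_grid(grid_step, region)
    ab = np.zeros_like(grid)
    for name, weight in spec.components.items():
        if weight <= 0:
            continue
        for b in _effective_bands(name, spec):
            ab += weight * band_profile(b, grid)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        ab = ab + rng.normal(0.0, spec.noise_sd, size=ab.shape)
    meta = {
        "components": dict(spec.components),
        "hydration": spec.hydration,
        "temperature": spec.temperature,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return Spectrum(grid, ab, meta=meta)


def degrade(s: Spectrum, d: DegradationSpec) -> Spectrum:
    """Apply storage-like band drift: neighborhoods of the affected bands are
    rescaled and shifted proportionally to severity. severity 0 is an exact
    identity; output is deterministic under a fixed seed."""
    s.grid_step()  # raises on non-uniform grid
    grid = s.wavenumbers
    ab = s.absorbance.copy()
    rng = np.random.default_rng(d.seed)
    for center in d.affected_bands:
        jitter_a = 1.0 + 0.1 * rng.uniform(-1.0, 1.0)
        jitter_c = 1.0 + 0.1 * rng.uniform(-1.0, 1.0)
        w = np.exp(-_FOUR_LN2 * (grid - center) ** 2 / d.neighborhood_fwhm**2)
        ab = ab * (1.0 + d.severity * d.amplitude_drift * jitter_a * w)
        delta = d.severity * d.center_drift * jitter_c * w
        ab = np.interp(grid - delta, grid, ab)
    meta = dict(s.meta)
    meta["degradation_severity"] = d.severity
    return Spectrum(grid.copy(), ab, meta=meta)
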