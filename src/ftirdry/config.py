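"""Pipeline configuration: defaults, YAML round trip and validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from ftirdry.spectral_core import SpectralRegion

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class PipelineConfig:
    grid_step: float = 1.0
    fingerprint_lo: float = 900.0
    fingerprint_hi: float = 1500.0
    oh_lo: float = 3000.0
    oh_hi: float = 3700.0
    sg_window: int = 21
    sg_poly_order: int = 3
    min_prominence: float = 0.02
    wtc_fit_lo: float = 25.0
    wtc_fit_hi: float = 50.0
    pca_components: int = 3
    drift_threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.sg_window % 2 != 1 or self.sg_window < self.sg_poly_order + 2:
            raise ValueError("sg_window must be odd and >= sg_poly_order + 2")
        if not 0.0 <= self.min_prominence <= 1.0:
            raise ValueError("min_prominence must be in [0, 1]")
        if self.drift_threshold <= 0:
            raise ValueError("drift_threshold must be > 0")
        if self.pca_components < 1:
            raise ValueError("pca_components must be >= 1")
        # region validity delegated to SpectralRegion
        self.fingerprint_region()
        self.oh_region()
        self.wtc_fit_range()

    def fingerprint_region(self) -> SpectralRegion:
        return SpectralRegion(self.fingerprint_lo, self.fingerprint_hi)

    def oh_region(self) -> SpectralRegion:
        return SpectralRegion(self.oh_lo, self.oh_hi)

    def wtc_fit_range(self) -> tuple[float, float]:
        if not self.wtc_fit_lo < self.wtc_fit_hi:
            raise ValueError("wtc fit range requires lo < hi")
        return (self.wtc_fit_lo, self.wtc_fit_hi)


def load_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def dump_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
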