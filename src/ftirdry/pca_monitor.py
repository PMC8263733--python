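"""Covariance PCA of the fingerprint region and storage-drift summary.

Spectra are resampled to a common grid, restricted to the fingerprint
region and vector-normalized row-wise; PCA is mean-centered covariance
eigendecomposition (not correlation). Loading signs are fixed so each
loading's largest-magnitude element is positive, making scores
deterministic. Drift between two groups is summarized per principal
component as the centroid distance in units of the pooled within-group
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ftirdry.spectral_core import FINGERPRINT, SpectralRegion, Spectrum, resample

__all__ = ["SpectraMatrix", "PCAModel", "DriftReport", "build_matrix", "fit_pca",
           "drift_report"]


@dataclass
class SpectraMatrix:
    data: np.ndarray  # rows = spectra (unit norm), columns = wavenumbers
    wavenumbers: np.ndarray
    row_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D")
        if self.data.shape[1] != len(self.wavenumbers):
            raise ValueError("column count must match wavenumber grid")
        norms = np.linalg.norm(self.data, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("rows must be unit-norm")


@dataclass
class PCAModel:
    loadings: np.ndarray  # (n_components, n_wavenumbers), orthonormal rows
    scores: np.ndarray  # (n_spectra, n_components)
    explained_variance_fraction: np.ndarray
    mean_spectrum: np.ndarray
    wavenumbers: np.ndarray
    row_labels: list = field(default_factory=list)


@dataclass(frozen=True)
class DriftReport:
    standardized_distance: dict  # PC index -> centroid distance / pooled SD
    clustered: bool
    threshold: float
    n_a: int
    n_b: int


def build_matrix(
    spectra: list[Spectrum],
    region: SpectralRegion = FINGERPRINT,
    grid_step: float = 1.0,
    labels: list | None = None,
) -> SpectraMatrix:
    """Common-grid, region-restricted, row-normalized spectra matrix."""
    if len(spectra) < 3:
        raise ValueError(f"PCA needs at least 3 spectra, got {len(spectra)}")
    lo = max(region.lo, max(float(s.wavenumbers[0]) for s in spectra))
    hi = min(region.hi, min(float(s.wavenumbers[-1]) for s in spectra))
    if lo >= hi:
        raise ValueError("spectra supports have empty intersection with region")
    common = SpectralRegion(lo, hi)
    rows = []
    for s in spectra:
        r = resample(s, grid_step, common)
        norm = np.linalg.norm(r.absorbance)
        if norm == 0:
            raise ValueError("cannot normalize an all-zero spectrum row")
        rows.append(r.absorbance / norm)
    grid = resample(spectra[0], grid_step, common).wavenumbers
    if labels is None:
        labels = [s.meta.get("label", i) for i, s in enumerate(spectra)]
    return SpectraMatrix(np.vstack(rows), grid, list(labels))


def fit_pca(m: SpectraMatrix, n_components: int) -> PCAModel:
    """Mean-centered covariance PCA via eigendecomposition.

    Explained-variance fractions are eigenvalues over the covariance trace,
    so they sum to 1 when n_components equals the rank.
    """
    n, p = m.data.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, columns)="
            f"{min(n - 1, p)}"
        )
    mean = m.data.mean(axis=0)
    x = m.data - mean
    cov = x.T @ x / (n - 1)
    total_var = float(np.trace(cov))
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    evals = np.clip(evals[order], 0.0, None)
    loadings = evecs[:, order].T
    # deterministic sign: largest-|element| of each loading positive
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
    scores = x @ loadings.T
    frac = evals / total_var if total_var > 0 else np.zeros_like(evals)
    return PCAModel(
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=frac,
        mean_spectrum=mean,
        wavenumbers=m.wavenumbers.copy(),
        row_labels=list(m.row_labels),
    )


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    if na + nb <= 2:
        return float(np.std(np.concatenate([a, b]), ddof=0))
    va = np.var(a, ddof=1) if na > 1 else 0.0
    vb = np.var(b, ddof=1) if nb > 1 else 0.0
    return float(np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)))


def drift_report(
    model: PCAModel,
    group_a,
    group_b,
    pcs: tuple[int, ...] = (0, 1, 2),
    threshold: float = 1.0,
) -> DriftReport:
    """Standardized per-PC centroid separation between two label groups.

    ``clustered`` is True when every requested PC separates the groups by
    less than *threshold* pooled within-group standard deviations.
    """
    group_a, group_b = set(group_a), set(group_b)
    ia = [i for i, lbl in enumerate(model.row_labels) if lbl in group_a]
    ib = [i for i, lbl in enumerate(model.row_labels) if lbl in group_b]
    if not ia or not ib:
        raise ValueError("both groups must be non-empty in the score rows")
    dists: dict[int, float] = {}
    for pc in pcs:
        if pc >= model.scores.shape[1]:
            raise ValueError(f"PC index {pc} not in the fitted model")
        sa = model.scores[ia, pc]
        sb = model.scores[ib, pc]
        sep = abs(float(sa.mean() - sb.mean()))
        sd = _pooled_sd(sa, sb)
        dists[pc] = 0.0 if sep == 0 else (np.inf if sd == 0 else sep / sd)
    clustered = all(dv < threshold for dv in dists.values())
    return DriftReport(
        standardized_distance=dists,
        clustered=clustered,
        threshold=threshold,
        n_a=len(ia),
        n_b=len(ib),
    )
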