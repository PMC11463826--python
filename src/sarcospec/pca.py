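"""PCA with the 95%-cumulative-variance retention rule and loading spectra.

Spectra are mean-centred only (no per-wavelength standardization: all
wavelengths share the spectrometer's arbitrary unit, and standardizing
would inflate noise-only wavelengths).  The retained component count is
the smallest k whose cumulative explained-variance ratio reaches the
target, 0.95 by default.  Loading vectors carry a deterministic sign
convention — the largest-magnitude element of each loading is positive —
so loading-spectrum plots and tests are stable across library versions.

``loading_spectra`` back-transforms the model into a long table of loading
value against wavelength per component, the chemometric view that lets a
component be read as a combination of fluorophore emission bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .spectra import WavelengthGrid


class DegenerateDataError(ValueError):
    """The data matrix has zero total variance."""


@dataclass(frozen=True)
class PCAModel:
    mean_spectrum: np.ndarray
    loadings: np.ndarray  # (n_components, n_wavelengths), rows orthonormal
    explained_variance: np.ndarray  # absolute, per retained component
    explained_variance_ratio: np.ndarray  # fractions, per retained component
    n_components: int
    grid: WavelengthGrid | None = None

    def __post_init__(self) -> None:
        if self.loadings.shape[0] != self.n_components:
            raise ValueError("n_components must equal the number of loadings")
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ValueError("loadings must be mutually orthonormal")
        evr = self.explained_variance_ratio
        if np.any(np.diff(evr) > 1e-12) or np.any(evr < 0) or evr.sum() > 1 + 1e-12:
            raise ValueError("explained_variance_ratio must be non-increasing fractions")


def fit_pca(
    matrix: np.ndarray,
    var_target: float = 0.95,
    grid: WavelengthGrid | None = None,
) -> PCAModel:
    """Mean-centred PCA retaining the fewest components reaching var_target."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows and 2 columns")
    if not (0.0 < var_target <= 1.0):
        raise ValueError("var_target must lie in (0, 1]")
    centered = matrix - matrix.mean(axis=0)
    if not np.any(np.abs(centered) > 0):
        raise DegenerateDataError("data matrix has zero variance")

    full = _SKPCA(n_components=None, svd_solver="full")
    full.fit(matrix)
    cumulative = np.cumsum(full.explained_variance_ratio_)
    k = int(np.searchsorted(cumulative, var_target - 1e-12) + 1)
    k = min(k, len(cumulative))

    loadings = full.components_[:k].copy()
    # deterministic sign: largest-|.| element of each loading made positive
    for row in loadings:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    return PCAModel(
        mean_spectrum=full.mean_.copy(),
        loadings=loadings,
        explained_variance=full.explained_variance_[:k].copy(),
        explained_variance_ratio=full.explained_variance_ratio_[:k].copy(),
        n_components=k,
        grid=grid,
    )


def pca_transform(model: PCAModel, matrix: np.ndarray) -> np.ndarray:
    """Project rows onto the retained loadings: (X - mean) @ loadings.T."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[1] != model.mean_spectrum.size:
        raise ValueError(
            f"matrix has {matrix.shape[1]} columns, model expects {model.mean_spectrum.size}"
        )
    return (matrix - model.mean_spectrum) @ model.loadings.T


def pca_inverse_transform(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Reconstruct spectra from scores (exact when all components retained)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    return scores @ model.loadings + model.mean_spectrum


def loading_spectra(model: PCAModel) -> pd.DataFrame:
    """Long table of (component, wavelength_nm, loading, major).

    Components 1-3 are flagged "major" when together they explain at least
    90% of the variance — the regime where the first three loading spectra
    dominate physiological interpretation.
    """
    if model.grid is not None:
        wavelengths = model.grid.values
    else:
        wavelengths = np.arange(model.mean_spectrum.size, dtype=float)
    cum3 = float(model.explained_variance_ratio[: min(3, model.n_components)].sum())
    frames = []
    for c in range(model.n_components):
        frames.append(
            pd.DataFrame(
                {
                    "component": c + 1,
                    "wavelength_nm": wavelengths,
                    "loading": model.loadings[c],
                    "major": (c < 3) and (cum3 >= 0.90),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
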