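"""Spectral cleaning chain and class-average / differential curves.

The cleanup applied to every acquisition, in this fixed order:

1. **Trim** to the closed window [445, 750] nm — below 445 nm the signal is
   dominated by rolloff from the 405 nm excitation line (the dichroic edge
   sits at 445 nm), above 750 nm no metabolite emission is expected.
2. **Quality control** — any trimmed spectrum whose mean intensity is below
   0.005 a.u. is discarded as a low-SNR failed acquisition.
3. **Smooth** with a 10-sample moving average.
4. **Pin-normalize**: divide every intensity by the spectrum's own value at
   the grid sample nearest 500 nm, so classification sees spectral shape
   around the Warburg-relevant region rather than absolute intensity.

The moving-average window of 10 is even; the convention here is a centred
window covering samples [i-5, i+4], truncated to available samples at the
edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .spectra import Spectrum, SpectrumSet, TissueClass, WavelengthGrid


class PreprocessError(ValueError):
    def __init__(self, stage: str, message: str) -> None:
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class PreprocessConfig:
    low_cut_nm: float = 445.0
    high_cut_nm: float = 750.0
    qc_mean_threshold: float = 0.005
    smooth_window: int = 10
    pin_nm: float = 500.0

    def __post_init__(self) -> None:
        if not (self.low_cut_nm < self.pin_nm < self.high_cut_nm):
            raise ValueError("require low_cut < pin < high_cut")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if self.qc_mean_threshold < 0:
            raise ValueError("qc_mean_threshold must be non-negative")


def trim_wavelengths(spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Keep exactly the samples with low_cut <= lambda <= high_cut."""
    lam = spectrum.grid.values
    mask = (lam >= config.low_cut_nm) & (lam <= config.high_cut_nm)
    if not mask.any():
        raise PreprocessError(
            "trim",
            f"no samples of {spectrum.acquisition_id!r} fall in "
            f"[{config.low_cut_nm}, {config.high_cut_nm}] nm",
        )
    if mask.sum() < 2:
        raise PreprocessError("trim", "fewer than two samples remain after trimming")
    return spectrum.with_grid(WavelengthGrid(lam[mask]), spectrum.intensities[mask])


def qc_filter(
    spectrum_set: SpectrumSet, config: PreprocessConfig = PreprocessConfig()
) -> Tuple[SpectrumSet, SpectrumSet]:
    """Partition into (kept, rejected) by mean trimmed intensity.

    A spectrum is rejected when its arithmetic mean intensity is strictly
    below the threshold ("less than 0.005"), so a mean of exactly 0.005
    is kept; a 1e-12 guard absorbs floating-point round-off at the boundary.
    """
    kept, rejected = [], []
    for s in spectrum_set:
        if float(np.mean(s.intensities)) < config.qc_mean_threshold - 1e-12:
            rejected.append(s)
        else:
            kept.append(s)
    return SpectrumSet(kept), SpectrumSet(rejected)


def smooth_moving_average(
    spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()
) -> Spectrum:
    """Moving-average smoothing, window [i-5, i+4] for the default 10.

    Output length equals input length; at the edges the window truncates to
    the available samples, so each output is the mean of between
    ceil(window/2) and window inputs.
    """
    window = config.smooth_window
    if window < 1:
        raise PreprocessError("smooth", "smooth_window must be >= 1")
    x = spectrum.intensities
    n = x.size
    half_left = window // 2
    half_right = window - half_left - 1
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - half_left, 0)
    hi = np.minimum(idx + half_right, n - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return spectrum.replace_intensities(smoothed)


def pin_index(grid: WavelengthGrid, pin_nm: float) -> int:
    """Index of the grid sample nearest pin_nm; ties go to the lower wavelength."""
    return int(np.argmin(np.abs(grid.values - pin_nm)))


def pin_normalize(
    spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()
) -> Spectrum:
    """Divide the spectrum by its intensity at the sample nearest 500 nm."""
    i = pin_index(spectrum.grid, config.pin_nm)
    pin_value = float(spectrum.intensities[i])
    if pin_value <= 1e-9:
        raise PreprocessError(
            "normalize",
            f"intensity at the {config.pin_nm} nm pin of "
            f"{spectrum.acquisition_id!r} is non-positive ({pin_value!r})",
        )
    return spectrum.replace_intensities(spectrum.intensities / pin_value)


def preprocess_dataset(
    spectrum_set: SpectrumSet, config: PreprocessConfig = PreprocessConfig()
) -> Tuple[SpectrumSet, List[str]]:
    """Full chain: trim -> QC -> smooth -> pin-normalize.

    Returns the processed set and the acquisition ids rejected by QC.
    """
    if len(spectrum_set) == 0:
        raise PreprocessError("input", "empty SpectrumSet")
    trimmed = SpectrumSet([trim_wavelengths(s, config) for s in spectrum_set])
    kept, rejected = qc_filter(trimmed, config)
    rejected_ids = [s.acquisition_id for s in rejected]
    processed = SpectrumSet(
        [pin_normalize(smooth_moving_average(s, config), config) for s in kept]
    )
    return processed, rejected_ids


@dataclass(frozen=True)
class DifferentialCurve:
    """Class-averaged curves scaled by the global maximum, plus sarcoma-healthy.

    ``offset`` is the purely visual elevation added to the differential when
    plotting (never baked into ``differential`` itself).
    """

    grid: WavelengthGrid
    healthy_mean: np.ndarray
    sarcoma_mean: np.ndarray
    healthy_se: np.ndarray
    sarcoma_se: np.ndarray
    differential: np.ndarray
    offset: float = 1.2

    def plotted_differential(self) -> np.ndarray:
        return self.differential + self.offset


def class_average_and_differential(
    spectrum_set: SpectrumSet,
    mode: str = "raw_globalmax",
    offset: float = 1.2,
    config: PreprocessConfig = PreprocessConfig(),
) -> DifferentialCurve:
    """Average each class, scale by the global max, and difference them.

    mode="raw_globalmax": average the (trimmed) raw spectra per class and
    divide both mean curves by the single maximum across the two curves.
    mode="pin_then_globalmax": pin-normalize each spectrum first, then
    average and scale the same way.  Standard errors are scaled alongside
    the means.
    """
    if mode not in ("raw_globalmax", "pin_then_globalmax"):
        raise ValueError(f"unknown mode {mode!r}")
    by_class = spectrum_set.classes()
    for tissue in (TissueClass.SARCOMA, TissueClass.HEALTHY):
        if len(by_class.get(tissue, [])) < 2:
            raise ValueError(
                f"need at least 2 spectra of class {tissue.value!r} for standard errors"
            )

    def stack(tissue: TissueClass) -> np.ndarray:
        spectra = by_class[tissue]
        if mode == "pin_then_globalmax":
            spectra = [pin_normalize(s, config) for s in spectra]
        return np.vstack([s.intensities for s in spectra])

    sarcoma = stack(TissueClass.SARCOMA)
    healthy = stack(TissueClass.HEALTHY)
    sarcoma_mean = sarcoma.mean(axis=0)
    healthy_mean = healthy.mean(axis=0)
    sarcoma_se = sarcoma.std(axis=0, ddof=1) / np.sqrt(sarcoma.shape[0])
    healthy_se = healthy.std(axis=0, ddof=1) / np.sqrt(healthy.shape[0])
    global_max = max(float(sarcoma_mean.max()), float(healthy_mean.max()))
    if global_max <= 0:
        raise ValueError("class means are identically non-positive")
    sarcoma_mean, healthy_mean = sarcoma_mean / global_max, healthy_mean / global_max
    sarcoma_se, healthy_se = sarcoma_se / global_max, healthy_se / global_max
    return DifferentialCurve(
        grid=spectrum_set.grid,
        healthy_mean=healthy_mean,
        sarcoma_mean=sarcoma_mean,
        healthy_se=healthy_se,
        sarcoma_se=sarcoma_se,
        differential=sarcoma_mean - healthy_mean,
        offset=offset,
    )
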