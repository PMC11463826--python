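"""Synthetic labelled sarcoma/healthy emission-spectrum generator.

The generator composes Gaussian emission bands for the metabolically
important endogenous fluorophores excited at 405 nm — free and
protein-bound NADH, free FAD, the basic and neutral forms of porphyrins,
plus an optional emitter at 671 nm where differential-fluorescence studies
repeatedly observe an unattributed peak.  Class structure follows the
Warburg effect: sarcoma tissue carries relatively more NADH/FAD and fewer
porphyrins than healthy muscle, and its overall back-reflected intensity is
muted by stronger scattering, modelled as a multiplicative attenuation of
the whole emission mixture.  An ambient-light baseline, an exponentially
decaying tail from the excitation line, per-acquisition lognormal abundance
jitter, additive Gaussian noise and occasional low-SNR "failed"
acquisitions complete the picture.

Everything is driven by a :class:`SimulationConfig` and a seed; identical
configs produce identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Mapping, Optional

import numpy as np

from .spectra import Spectrum, SpectrumSet, TissueClass, WavelengthGrid

GAUSS_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class DegenerateProfileError(ValueError):
    """A zero-width emission band was asked to emit."""


class EmptyDatasetError(ValueError):
    """Both class counts are zero."""


@dataclass(frozen=True)
class FluorophoreProfile:
    """Named emitter: emission maximum and full width at half maximum, nm."""

    name: str
    peak_nm: float
    fwhm_nm: float

    def __post_init__(self) -> None:
        if self.peak_nm <= 0:
            raise ValueError("peak_nm must be positive")
        if self.fwhm_nm < 0:
            raise ValueError("fwhm_nm must be non-negative")

    @property
    def sigma_nm(self) -> float:
        return self.fwhm_nm / GAUSS_FWHM_TO_SIGMA


#: Reference emission peaks / FWHM (nm) for 405 nm excitation.  The first
#: five are the classic metabolic fluorophores; "unexplained 671" is the
#: recurring differential peak at 671 nm given a porphyrin-like width.
DEFAULT_PROFILES: tuple = (
    FluorophoreProfile("free NADH", 487.0, 84.0),
    FluorophoreProfile("protein-bound NADH", 501.0, 64.0),
    FluorophoreProfile("free FAD", 544.0, 75.0),
    FluorophoreProfile("basic porphyrins", 590.0, 25.0),
    FluorophoreProfile("neutral porphyrins", 630.0, 25.0),
)

UNEXPLAINED_671 = FluorophoreProfile("unexplained 671", 671.0, 25.0)


def profile_registry(include_unexplained: bool = True) -> Dict[str, FluorophoreProfile]:
    profiles = DEFAULT_PROFILES + ((UNEXPLAINED_671,) if include_unexplained else ())
    return {p.name: p for p in profiles}


@dataclass(frozen=True)
class ClassEmissionModel:
    """Per-class fluorophore amplitudes and whole-emission attenuation."""

    abundances: Mapping[str, float]
    attenuation: float = 1.0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.abundances.values()):
            raise ValueError("abundances must be non-negative")
        if not (0.0 < self.attenuation <= 1.0):
            raise ValueError("attenuation must be in (0, 1]")


def _default_healthy_model() -> ClassEmissionModel:
    return ClassEmissionModel(
        abundances={
            "free NADH": 1.0,
            "protein-bound NADH": 0.8,
            "free FAD": 0.5,
            "basic porphyrins": 0.25,
            "neutral porphyrins": 0.25,
            "unexplained 671": 0.16,
        },
        attenuation=1.0,
    )


def _default_sarcoma_model() -> ClassEmissionModel:
    # Warburg-effect contrast relative to healthy: more free NADH (x1.6) and
    # FAD (x1.4), fewer porphyrins (x0.5), extra 671 nm emission, and a
    # scattering attenuation of 0.65 muting the whole class.
    return ClassEmissionModel(
        abundances={
            "free NADH": 1.6,
            "protein-bound NADH": 0.8,
            "free FAD": 0.7,
            "basic porphyrins": 0.125,
            "neutral porphyrins": 0.125,
            "unexplained 671": 0.24,
        },
        attenuation=0.65,
    )


@dataclass
class SimulationConfig:
    """All generative knobs; defaults emulate the study conditions.

    The default grid (400-800 nm, 1736 points) leaves exactly 1323 samples
    after the 445-750 nm trim; default counts give the study's 3:1
    class imbalance of 393 sarcoma to 118 healthy usable acquisitions.
    """

    grid_start_nm: float = 400.0
    grid_stop_nm: float = 800.0
    grid_points: int = 1736
    models: Dict[TissueClass, ClassEmissionModel] = field(
        default_factory=lambda: {
            TissueClass.SARCOMA: _default_sarcoma_model(),
            TissueClass.HEALTHY: _default_healthy_model(),
        }
    )
    profiles: Dict[str, FluorophoreProfile] = field(default_factory=profile_registry)
    baseline_level: float = 0.05
    baseline_cv: float = 0.5
    excitation_rolloff_amplitude: float = 0.8
    rolloff_decay_nm: float = 8.0
    noise_sd: float = 0.02
    n_sarcoma: int = 393
    n_healthy: int = 118
    n_mice_per_class: int = 6
    #: lognormal CV of per-acquisition abundance jitter; either one float
    #: for all fluorophores or a mapping name -> cv (missing names use 0.25).
    #: Narrow low-abundance bands (porphyrins, the 671 nm emitter) vary more
    #: acquisition-to-acquisition than the broad NADH/FAD bands.
    abundance_cv: object = field(
        default_factory=lambda: {
            "free NADH": 0.25,
            "protein-bound NADH": 0.25,
            "free FAD": 0.25,
            "basic porphyrins": 0.45,
            "neutral porphyrins": 0.45,
            "unexplained 671": 0.5,
        }
    )
    mouse_effect_sd: float = 0.0
    p_failed: float = 0.0
    failed_mean_target: float = 0.003
    qc_window_nm: tuple = (445.0, 750.0)
    seed: int = 20241009

    def __post_init__(self) -> None:
        if self.n_sarcoma < 0 or self.n_healthy < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.p_failed <= 1.0):
            raise ValueError("p_failed must lie in [0, 1]")
        if self.grid_points < 2:
            raise ValueError("grid_points must be at least 2")
        if self.baseline_cv < 0:
            raise ValueError("baseline_cv must be non-negative")

    def cv_for(self, fluorophore: str) -> float:
        """Abundance-jitter CV for one fluorophore (scalar or per-name)."""
        if isinstance(self.abundance_cv, Mapping):
            return float(self.abundance_cv.get(fluorophore, 0.25))
        return float(self.abundance_cv)

    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(
            np.linspace(self.grid_start_nm, self.grid_stop_nm, self.grid_points)
        )


def emission_profile(
    profile: FluorophoreProfile, amplitude: float, grid: WavelengthGrid
) -> np.ndarray:
    """Gaussian emission band evaluated on the grid.

    v(lambda) = amplitude * exp(-(lambda - peak)^2 / (2 sigma^2)) with
    sigma = FWHM / (2 sqrt(2 ln 2)), so v(peak) = amplitude and
    v(peak +/- FWHM/2) = amplitude / 2.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    lam = grid.values
    if profile.fwhm_nm == 0:
        if amplitude > 0:
            raise DegenerateProfileError(
                f"{profile.name!r} has zero FWHM but non-zero amplitude"
            )
        return np.zeros_like(lam)
    sigma = profile.sigma_nm
    return amplitude * np.exp(-((lam - profile.peak_nm) ** 2) / (2.0 * sigma**2))


def _deterministic_mixture(
    model: ClassEmissionModel,
    abundances: Mapping[str, float],
    config: SimulationConfig,
    lam: np.ndarray,
    baseline: Optional[float] = None,
) -> np.ndarray:
    emission = np.zeros_like(lam)
    for name, amplitude in abundances.items():
        profile = config.profiles[name]
        emission += emission_profile(profile, amplitude, WavelengthGrid(lam))
    rolloff = config.excitation_rolloff_amplitude * np.exp(
        -np.maximum(lam - 405.0, 0.0) / config.rolloff_decay_nm
    )
    level = config.baseline_level if baseline is None else baseline
    return model.attenuation * emission + level + rolloff


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplier with the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma_log = np.sqrt(np.log(1.0 + cv**2))
    return float(np.exp(rng.normal(-0.5 * sigma_log**2, sigma_log)))


def simulate_spectrum(
    tissue_class: TissueClass,
    config: SimulationConfig,
    rng: np.random.Generator,
    acquisition_id: str = "a0",
    mouse_id: str = "m0",
    mouse_log_effect: float = 0.0,
) -> Spectrum:
    """Draw one acquisition for the given class.

    Abundances are jittered lognormally with the configured coefficient of
    variation, the class attenuation and ambient/rolloff background are
    applied, Gaussian noise is added, and intensities are clipped at zero.
    With probability ``p_failed`` the whole spectrum is rescaled so its mean
    over the QC window falls below the cleanup threshold, emulating a
    poorly positioned sample.
    """
    tissue_class = TissueClass(tissue_class)
    model = config.models[tissue_class]
    grid = config.grid()
    lam = grid.values

    jitter = {
        name: amp * _lognormal_factor(rng, config.cv_for(name)) * np.exp(mouse_log_effect)
        for name, amp in model.abundances.items()
    }
    baseline = config.baseline_level * _lognormal_factor(rng, config.baseline_cv)
    intensities = _deterministic_mixture(model, jitter, config, lam, baseline=baseline)
    if config.noise_sd > 0:
        intensities = intensities + rng.normal(0.0, config.noise_sd, size=lam.size)
    intensities = np.clip(intensities, 0.0, None)

    if config.p_failed > 0 and rng.random() < config.p_failed:
        lo, hi = config.qc_window_nm
        window = (lam >= lo) & (lam <= hi)
        mean = float(intensities[window].mean())
        if mean > 0:
            intensities = intensities * (config.failed_mean_target / mean)

    return Spectrum(grid, intensities, acquisition_id, mouse_id, tissue_class)


def simulate_dataset(config: SimulationConfig, seed: Optional[int] = None) -> SpectrumSet:
    """Simulate the full labelled dataset described by ``config``.

    Acquisitions are assigned round-robin to ``n_mice_per_class`` mouse ids
    within each class.  Identical configs (and seed) give identical sets.
    """
    if config.n_sarcoma == 0 and config.n_healthy == 0:
        raise EmptyDatasetError("both class counts are zero")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    spectra = []
    for tissue, count, tag in (
        (TissueClass.SARCOMA, config.n_sarcoma, "S"),
        (TissueClass.HEALTHY, config.n_healthy, "H"),
    ):
        n_mice = max(config.n_mice_per_class, 1)
        if config.mouse_effect_sd > 0:
            mouse_effects = rng.normal(0.0, config.mouse_effect_sd, size=n_mice)
        else:
            mouse_effects = np.zeros(n_mice)
        for i in range(count):
            mouse = i % n_mice
            spectra.append(
                simulate_spectrum(
                    tissue,
                    config,
                    rng,
                    acquisition_id=f"{tag}{i:04d}",
                    mouse_id=f"{tag}M{mouse + 1}",
                    mouse_log_effect=float(mouse_effects[mouse]),
                )
            )
    return SpectrumSet(spectra)


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain-dict form of a config (for YAML round-tripping in the CLI)."""
    raw = asdict(config)
    raw["models"] = {
        tissue.value: {"abundances": dict(m.abundances), "attenuation": m.attenuation}
        for tissue, m in config.models.items()
    }
    raw["profiles"] = {
        name: {"peak_nm": p.peak_nm, "fwhm_nm": p.fwhm_nm}
        for name, p in config.profiles.items()
    }
    raw["qc_window_nm"] = list(config.qc_window_nm)
    return raw


def config_from_dict(raw: Mapping) -> SimulationConfig:
    kwargs = dict(raw)
    if "models" in kwargs:
        kwargs["models"] = {
            TissueClass(k): ClassEmissionModel(
                abundances=dict(v["abundances"]), attenuation=v.get("attenuation", 1.0)
            )
            for k, v in kwargs["models"].items()
        }
    if "profiles" in kwargs:
        kwargs["profiles"] = {
            name: FluorophoreProfile(name, v["peak_nm"], v["fwhm_nm"])
            for name, v in kwargs["profiles"].items()
        }
    if "qc_window_nm" in kwargs:
        kwargs["qc_window_nm"] = tuple(kwargs["qc_window_nm"])
    return SimulationConfig(**kwargs)
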