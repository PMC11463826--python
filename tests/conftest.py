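import numpy as np
import pytest

import sarcospec as ss
from sarcospec.simulate import _default_healthy_model


def make_set(grid_values, rows, tissue=None, prefix="a"):
    """Build a SpectrumSet from a wavelength vector and intensity rows."""
    grid = ss.WavelengthGrid(np.asarray(grid_values, dtype=float))
    tissue = tissue or ["sarcoma"] * len(rows)
    return ss.SpectrumSet(
        [
            ss.Spectrum(grid, np.asarray(r, dtype=float), f"{prefix}{i:03d}", f"m{i % 3}", t)
            for i, (r, t) in enumerate(zip(rows, tissue))
        ]
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The full default simulated study: 393 sarcoma + 118 healthy spectra."""
    return ss.simulate_dataset(ss.SimulationConfig())


@pytest.fixture(scope="session")
def processed_default(default_dataset):
    processed, rejected = ss.preprocess_dataset(default_dataset)
    assert rejected == []
    return processed


@pytest.fixture(scope="session")
def small_labeled_dataset():
    """A compact simulated dataset (90 + 30 spectra, coarse grid) for
    classifier-level tests that do not need the full study size."""
    config = ss.SimulationConfig(
        grid_start_nm=420.0,
        grid_stop_nm=770.0,
        grid_points=351,
        n_sarcoma=90,
        n_healthy=30,
        seed=7,
    )
    processed, _ = ss.preprocess_dataset(ss.simulate_dataset(config))
    return processed


def null_simulation_config(seed, n_sarcoma=36, n_healthy=12):
    """Both classes drawn from the identical emission model (null world)."""
    h = _default_healthy_model()
    return ss.SimulationConfig(
        grid_start_nm=420.0,
        grid_stop_nm=770.0,
        grid_points=351,
        models={ss.TissueClass.SARCOMA: h, ss.TissueClass.HEALTHY: h},
        n_sarcoma=n_sarcoma,
        n_healthy=n_healthy,
        seed=seed,
    )
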