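"""Shared fixtures: noiseless phantoms at the 48^3 analysis scale.

Phantom generation plus the full alignment pipeline costs a few seconds per
condition, so the expensive fixtures are session-scoped and shared across
test modules.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import binary_erosion

from ventstrain.phantom import PhantomConfig, make_phantom
from ventstrain.regional import compute_metric_maps

ANALYSIS_GRID = (48, 48, 48)
N_PHASES = 21


def _build(modality: str, condition: str = "baseline", **kw):
    cfg = PhantomConfig(
        grid_shape=ANALYSIS_GRID,
        n_phases=N_PHASES,
        modality=modality,
        condition=condition,
        noise_sd_hu=0.0,
        seed=3,
        **kw,
    )
    seq, truth = make_phantom(cfg)
    maps = compute_metric_maps(seq, truth.transforms, trim_mm=6.0)
    return seq, truth, maps


@pytest.fixture(scope="session")
def hfov_case():
    return _build("HFOV")


@pytest.fixture(scope="session")
def cmv_case():
    return _build("CMV")


@pytest.fixture(scope="session")
def mfov_case():
    return _build("MFOV")


@pytest.fixture(scope="session")
def injured_cmv_case():
    return _build("CMV", condition="injured")


@pytest.fixture(scope="session")
def small_hfov_case():
    """Coarser, fewer-phase phantom for cheap per-test pipelines."""
    cfg = PhantomConfig(
        grid_shape=(32, 32, 32),
        n_phases=8,
        modality="HFOV",
        noise_sd_hu=0.0,
        seed=1,
    )
    seq, truth = make_phantom(cfg)
    return seq, truth


def interior_mask(truth, maps, iterations: int = 2) -> np.ndarray:
    """Analysis mask eroded away from the lung surface, where the
    finite-difference stencil stays inside the exactly-prescribed field."""
    return binary_erosion(truth.mask, iterations=iterations) & maps.mask
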