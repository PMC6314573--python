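"""Shared fixtures: small phantoms sized for fast, deterministic tests."""

from __future__ import annotations

import numpy as np
import pytest

from lcnquant import GenerationParams, ImagingParams
from lcnquant.phantom import simulate


@pytest.fixture(scope="session")
def small_params() -> GenerationParams:
    """A desk-scale phantom: 24×24×6 µm³, one lacuna, ~1% canal fraction."""
    return GenerationParams(
        volume_um=(6.0, 24.0, 24.0),
        lacuna_density_mm3=3.0e5,       # one lacuna in 3456 µm³
        lacuna_semiaxes_um=((1.2, 1.5), (1.2, 1.5), (2.0, 2.6)),
        canal_fraction_pct=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_params):
    """(image, canal_mask, lacuna_mask, truth_skeleton, ground_truth)."""
    return simulate(small_params, ImagingParams(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
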