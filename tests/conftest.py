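import dataclasses
import datetime

import numpy as np
import pytest

from forestchange import grids, synthetic


def constant_stack(values, shape=(8, 8), date=None, valid=None, pixel_size=10.0):
    """BandStack with a constant value per band."""
    bands = np.empty((10, *shape), dtype=np.float32)
    for i, v in enumerate(values):
        bands[i] = v
    if valid is None:
        valid = np.ones(shape, dtype=bool)
    return grids.BandStack(
        bands=bands,
        valid_mask=valid,
        pixel_size=pixel_size,
        transform=grids.Affine.scale(pixel_size),
        date=date or datetime.date(2020, 7, 1),
    )


def noiseless_signatures():
    """Default signature library with seasonal swing and noise switched off."""
    return {
        code: dataclasses.replace(
            sig, seasonal_amplitude=(0.0,) * 10, noise_sd=(0.0,) * 10
        )
        for code, sig in synthetic.DEFAULT_SIGNATURES.items()
    }


@pytest.fixture
def noise_free_scene():
    """A 64x64 two-year noise-free, cloud-free scene with one clearing and one burn."""
    base = synthetic.SceneConfig(
        rows=64, cols=64, years=(2020, 2021), rng_seed=11,
        label_noise_rate=0.0, cloud_fraction=0.0,
    )
    layout = synthetic.generate_layout(base, np.random.default_rng(base.rng_seed))
    events = synthetic.propose_change_polygons(
        layout, 2021, n_clearings=1, n_burns=1, patch_px=(5, 8), rng_seed=2
    )
    config = dataclasses.replace(base, change_events=events)
    acquisitions, truth = synthetic.make_scene(config, noiseless_signatures())
    return config, acquisitions, truth


@pytest.fixture
def default_noise_scene():
    """A 96x96 two-year scene at the default noise and cloud settings."""
    base = synthetic.SceneConfig(rows=96, cols=96, years=(2020, 2021), rng_seed=5)
    layout = synthetic.generate_layout(base, np.random.default_rng(base.rng_seed))
    events = synthetic.propose_change_polygons(
        layout, 2021, n_clearings=1, n_burns=1, patch_px=(6, 10), rng_seed=3
    )
    config = dataclasses.replace(base, change_events=events)
    acquisitions, truth = synthetic.make_scene(config)
    return config, acquisitions, truth
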