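"""Shared fixtures: phantoms are generated once per session and reused."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from coroct3d import phantom as ph
from coroct3d import pipeline as pl


@pytest.fixture(scope="session")
def straight_spec():
    return ph.study_arteries(0)["straight"]


@pytest.fixture(scope="session")
def straight_phantom(straight_spec):
    """Straight 20 mm artery, r=1.5 mm lumen, 1 mm wall, 120 deg CP arc."""
    vol, truth = ph.generate_phantom(straight_spec)
    return vol, truth


@pytest.fixture(scope="session")
def plain_tube_phantom():
    """Straight tube without plaque (for geometry-only checks)."""
    spec = ph.PhantomSpec(noise_seed=7)
    vol, truth = ph.generate_phantom(spec)
    return vol, truth, spec


@pytest.fixture(scope="session")
def lumen_seed_voxel(straight_phantom):
    _, truth = straight_phantom
    com = ndimage.center_of_mass(truth.class_masks["lumen"])
    return tuple(int(round(x)) for x in com)


@pytest.fixture(scope="session")
def straight_reconstruction(straight_phantom, lumen_seed_voxel):
    """Full six-stage reconstruction of the straight artery (run once)."""
    vol, truth = straight_phantom
    seeds = pl.auto_class_seeds(truth)
    return pl.reconstruct(vol, lumen_seed_voxel, seeds)


@pytest.fixture(scope="session")
def default_model(straight_phantom, lumen_seed_voxel):
    """Tissue mixture fitted on the straight phantom."""
    vol, truth = straight_phantom
    cfg = pl.PipelineConfig()
    lm = pl.rough_lumen(vol, lumen_seed_voxel, cfg)
    seeds = pl.auto_class_seeds(truth)
    return pl.fit_tissue_model(vol, lm, seeds, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
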