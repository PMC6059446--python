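"""Shared fixtures.

The heavyweight session fixtures build the desk-scale study exactly once:
a model trained on 30 phantoms (96 x 96 x 72, rotations up to 8 degrees,
no calcification) plus held-out test cohorts.  Lighter module tests use
small synthetic volumes built on the fly.
"""

from __future__ import annotations

import numpy as np
import pytest

import colonialwalk as cw
from colonialwalk.pipeline import desk_scale_config

# Fixed study seeds: training cohort, held-out cohort, stress cohort.
TRAIN_SEED = 20300
HELDOUT_SEED = 50810
TAVI_SEED = 90120
MODEL_SEED = 7


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_volume(rng):
    """A 16^3 random-intensity volume with the intensity floor applied."""
    data = rng.uniform(1.0, 300.0, size=(16, 16, 16)).astype(np.float32)
    return cw.Volume(data, spacing=(1.0, 1.0, 1.5), origin_id="test")


@pytest.fixture(scope="session")
def train_cohort():
    """30 training phantoms: rotated poses, no calcification."""
    return cw.generate_dataset(30, cw.DatasetConfig(rotation_max_deg=8.0), TRAIN_SEED)


@pytest.fixture(scope="session")
def heldout_cohort():
    """10 held-out phantoms from the training distribution."""
    return cw.generate_dataset(10, cw.DatasetConfig(rotation_max_deg=8.0), HELDOUT_SEED)


@pytest.fixture(scope="session")
def tavi_cohort():
    """10 stress phantoms: stronger rotations plus calcification blobs."""
    return cw.generate_dataset(
        10, cw.DatasetConfig(rotation_max_deg=12.0, tavi_fraction=1.0), TAVI_SEED
    )


@pytest.fixture(scope="session")
def study_model(train_cohort):
    """The nine-tree model trained on the 30-phantom cohort."""
    return cw.train_two_phase(train_cohort, desk_scale_config(), seed=MODEL_SEED)


# ---------------------------------------------------------------------------
# Tiny pipeline fixtures (seconds, for plumbing tests)
# ---------------------------------------------------------------------------

def tiny_phantom_config(seed: int = 0, **kw) -> cw.PhantomConfig:
    return cw.PhantomConfig(shape=(64, 64, 48), seed=seed, **kw)


def tiny_phase_config() -> cw.PhaseConfig:
    """A deliberately small configuration so training takes seconds."""
    return cw.PhaseConfig(
        global_=cw.GlobalPhaseConfig(
            stride=6,
            offset_range=cw.OffsetRange(10, 10, 6),
            walk=cw.WalkConfig(n_walkers=25, step_length=4.0, n_steps=32),
            tree=cw.TreeConfig(min_samples=150, n_theta=8, n_tau=4, max_samples=6000),
        ),
        local_=cw.LocalPhaseConfig(
            stride=5,
            offset_range=cw.OffsetRange(6, 6, 4),
            init_box=(8, 8, 4),
            walk=cw.WalkConfig(n_walkers=25, step_length=2.0, n_steps=32),
            tree=cw.TreeConfig(min_samples=150, n_theta=8, n_tau=4, max_samples=6000),
        ),
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    return [
        cw.generate_phantom(tiny_phantom_config(seed=s)) for s in (11, 22, 33)
    ]


@pytest.fixture(scope="session")
def tiny_model(tiny_cohort):
    return cw.train_two_phase(tiny_cohort, tiny_phase_config(), seed=3)
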