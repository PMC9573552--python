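"""Shared fixtures.

The two trained matchers are expensive (minutes of CPU); they are built
once per session and shared by every test that needs an end-to-end
pipeline.  All randomness is seeded, so the whole suite is reproducible.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

import shwfs
from shwfs.evaluate import scaled_run_config, run_experiment
from shwfs.matcher import MatchNetwork, SamplerConfig, TrainingConfig, make_dataset, train

logging.getLogger("shwfs").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def geometry16():
    """Reference sensor: 16x16 lenslets, f = 6.5 mm, 20x20 px windows."""
    return shwfs.build_geometry()


@pytest.fixture(scope="session")
def geometry8():
    """Scaled sensor: 8x8 lenslets, other physical parameters unchanged."""
    return shwfs.build_geometry(grid_shape=8)


@pytest.fixture(scope="session")
def template():
    return shwfs.gaussian_template(1.0)


@pytest.fixture(scope="session")
def op16(geometry16):
    return shwfs.build_recon_operator(geometry16, shwfs.mode_list(15), n_modes_full=15)


@pytest.fixture(scope="session")
def op8(geometry8):
    return shwfs.build_recon_operator(geometry8, shwfs.mode_list(15), n_modes_full=15)


@pytest.fixture(scope="session")
def net16(geometry16):
    """Matcher for the reference sensor, trained on analytic centroid sets
    spanning the extended amplitude range (RMS 0.5-55 waves)."""
    train_set, _ = make_dataset(
        1200,
        geometry16,
        sampler=SamplerConfig(rms_range=(0.5, 55.0)),
        split=0.9,
        rng_seed=11,
        method="analytic",
    )
    net = MatchNetwork(geometry16.k_effective, seed=0)
    train(net, train_set, TrainingConfig(epochs=30, batch_size=32, seed=0))
    return net


@pytest.fixture(scope="session")
def scaled_report(tmp_path_factory):
    """Full scaled benchmark: trains the 8x8 matcher on rendered frames and
    sweeps all 12 reconstructed modes under both pipelines (coarse 0.5-wave
    steps to keep the suite fast)."""
    cfg = scaled_run_config(sweep_step=0.5, max_steps=200)
    return run_experiment(cfg)


@pytest.fixture(scope="session")
def net8(scaled_report):
    return scaled_report.net
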