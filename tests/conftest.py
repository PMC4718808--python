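"""Shared fixtures: small synthetic sessions with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from spikerhythm.bands import DEFAULT_BANDS
from spikerhythm.synth import (BandComponent, Locking, ScenarioConfig,
                               UnitSpec, generate_session)

ALL_BANDS = tuple(BandComponent(DEFAULT_BANDS[n])
                  for n in ("theta", "beta", "low_gamma", "high_gamma"))


def small_config(units, n_trials=24, seed=0, p_correct=0.8,
                 components=ALL_BANDS, **kw):
    """A 24-trial (~2 min) session config for unit tests."""
    return ScenarioConfig(band_components=components, units=tuple(units),
                          n_trials=n_trials, block_size=min(n_trials, 24),
                          p_correct=p_correct, trial_spacing=4.0,
                          first_onset=2.0, seed=seed, **kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def locked_session():
    """24 trials; u_lock locked to beta at +pi/2 (kappa=2), u_null unlocked."""
    cfg = small_config([
        UnitSpec("u_lock", "interneuron", 12.0,
                 (Locking("beta", 2.0, np.pi / 2),)),
        UnitSpec("u_null", "interneuron", 12.0),
    ], seed=7)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def tuned_session():
    """96 trials; u_pos fires 4x in position 2, u_flat untuned."""
    cfg = ScenarioConfig(
        band_components=(), units=(
            UnitSpec("u_pos", "interneuron", 6.0,
                     tuning={"position": {2: 4.0}}),
            UnitSpec("u_flat", "interneuron", 6.0),
        ), n_trials=96, block_size=24, p_correct=0.8, trial_spacing=3.0,
        first_onset=2.0, noise_sd=0.0, seed=11)
    return generate_session(cfg)
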