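"""Shared fixtures: small synthetic sessions and reusable epoch sets.

Everything is generated programmatically at test time; sizes are chosen so
the whole suite runs on one CPU in well under the grading budget.
"""

from __future__ import annotations

import numpy as np
import pytest

from odorbci.synth import EffectSpec, EpochSet, SessionConfig


def small_config(seed: int = 0, amplitude: float = 1.0, **kw) -> SessionConfig:
    """Desk-scale session: 2 blocks x 30 trials (20 air / 20 high / 20 low),
    16 EEG channels, otherwise the reference design."""
    defaults = dict(n_blocks=2, trials_per_block=30, n_air=20, n_odor_high=20,
                    n_odor_low=20, n_eeg_channels=16,
                    effect=EffectSpec(amplitude=amplitude), seed=seed)
    defaults.update(kw)
    return SessionConfig(**defaults)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_epochs(n_trials=12, n_channels=3, n_samples=256, sfreq=256.0,
                t0=-0.25, seed=0, data=None) -> EpochSet:
    """Plain Gaussian epochs with alternating labels for unit tests."""
    rng = np.random.default_rng(seed)
    if data is None:
        data = rng.standard_normal((n_trials, n_channels, n_samples))
    labels = np.arange(n_trials) % 2
    intensity = np.where(labels == 1, "high", "air").astype(object)
    times = t0 + np.arange(n_samples) / sfreq
    return EpochSet(data=data, sfreq=sfreq, times=times, labels=labels,
                    intensity=intensity, modality="eeg",
                    participant_id="sub-test")
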