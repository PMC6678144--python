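"""Shared fixtures: small synthetic nights generated at test time."""

import numpy as np
import pytest

from bruxscore import scoring, synthetic


@pytest.fixture(scope="session")
def short_night():
    """A 30 min night with a healthy mix of planted structure."""
    cfg = synthetic.GeneratorConfig(
        seed=42,
        night_duration=1800.0,
        episode_rate=8.0,
        confounder_rate=4.0,
        surge_only_rate=4.0,
    )
    rec, truth = synthetic.generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def scored_short_night(short_night):
    cfg, rec, truth = short_night
    return cfg, rec, truth, scoring.score_recording(rec)


@pytest.fixture(scope="session")
def quiet_night():
    """A night with no planted events at all."""
    cfg = synthetic.GeneratorConfig(
        seed=7,
        night_duration=900.0,
        episode_rate=0.0,
        confounder_rate=0.0,
        surge_only_rate=0.0,
    )
    rec, truth = synthetic.generate_recording(cfg)
    return cfg, rec, truth


def make_envelope(values, fs=100.0):
    from bruxscore.preprocess import EnvelopeSeries

    return EnvelopeSeries(np.asarray(values, dtype=float), fs, "EMG_LEFT", units="%MVC")
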