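import numpy as np
import pytest

from pnskit.datasets import berkeley_isocenter, erlangen
from pnskit.observations import BinaryObservation


@pytest.fixture(scope="session")
def berkeley():
    return berkeley_isocenter()


@pytest.fixture(scope="session")
def erlangen_cohort():
    return erlangen()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_obs(rows, **common):
    """Small helper: rows of (tau, amplitude, response[, weight])."""
    defaults = dict(subject_id="s", axis="x")
    defaults.update(common)
    out = []
    for row in rows:
        tau, amp, resp = row[:3]
        w = row[3] if len(row) > 3 else 1.0
        out.append(
            BinaryObservation(
                rise_time_ms=tau, amplitude_mTm=amp, response=resp, weight=w, **defaults
            )
        )
    return out
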