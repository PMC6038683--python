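import numpy as np
import pytest

from pbvent import SubjectParams, emd, filter_mee, generate_subject
from pbvent.significance import null_ensemble


def make_emd_fixtures() -> list[np.ndarray]:
    """100 decomposition inputs: white noise, pure/mixed tones with drift,
    filtered synthetic subjects, and amplitude-growing noise."""
    fixtures: list[np.ndarray] = []
    rng = np.random.default_rng(42)
    for _ in range(40):
        fixtures.append(rng.standard_normal(200))
    i = np.arange(200)
    for period in (8, 20, 50):
        fixtures.append(np.sin(2 * np.pi * i / period))
        fixtures.append(np.sin(2 * np.pi * i / 8)
                        + np.sin(2 * np.pi * i / period + 1.0) + 0.01 * i)
    for seed in range(40):
        subject = generate_subject(
            SubjectParams(pb_amplitude=0.3, noise_sigma=0.08, seed=seed))
        fixtures.append(filter_mee(subject).kept)
    for _ in range(14):
        fixtures.append(rng.standard_normal(300) * np.exp(0.005 * np.arange(300)))
    assert len(fixtures) == 100
    return fixtures


@pytest.fixture(scope="session")
def emd_fixtures():
    return make_emd_fixtures()


@pytest.fixture(scope="session")
def decomposed_fixtures(emd_fixtures):
    return [(x, emd(x)) for x in emd_fixtures]


@pytest.fixture(scope="session")
def null_curves_200():
    """Shared white-noise null for length-200 inputs (500 realizations)."""
    return null_ensemble(200, n_null=500, seed=0)


@pytest.fixture
def two_tone():
    i = np.arange(200)
    fast = np.sin(2 * np.pi * i / 8)
    slow = np.sin(2 * np.pi * i / 50)
    return i, fast, slow, fast + slow + 0.01 * i
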