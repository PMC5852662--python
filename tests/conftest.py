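import warnings

import numpy as np
import pytest

from streamdecode.synthetic_data import (
    NeuralParams,
    ParticipantTemplate,
    PerceptParams,
)

# liblinear occasionally reports slow convergence on tiny degenerate folds;
# irrelevant to the statistical checks below.
warnings.filterwarnings("ignore", message="Liblinear failed to converge")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def neural():
    return NeuralParams()


@pytest.fixture
def percept():
    return PerceptParams()


@pytest.fixture
def flat_template():
    """Canonical template: no jitter, unit amplitude, no sign flip."""
    return ParticipantTemplate()


@pytest.fixture
def fast_percept():
    """Short, symmetric phases: convenient for small epoch fixtures."""
    return PerceptParams(
        mu_log_initial_integrated=float(np.log(6.0)),
        mu_log_integrated=float(np.log(5.0)),
        mu_log_segregated=float(np.log(5.0)),
        delta_f_multiplier=1.0,
    )
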