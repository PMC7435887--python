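"""Shared end-to-end fixtures.

The two full-pipeline experiments (synthesis -> preprocessing -> training ->
scoring -> decisions -> evaluation) are expensive, so they run once per
session and are shared by every test that inspects their results.  Study
conditions: a 5-subject cohort (240 s per subject at 250 Hz, two sessions
with 15% morphology drift) for the convolutional path, and a 3-subject
single-session cohort for the recurrent path.
"""

import pytest

from ecgid.pipeline import run_rnn_experiment, run_tcnn_experiment


@pytest.fixture(scope="session")
def tcnn_result():
    """Convolutional-path experiment; session 1 is the clean regime and the
    drifted session 2 the cross-session probe."""
    return run_tcnn_experiment(seed=1, session_drift=0.15)


@pytest.fixture(scope="session")
def rnn_result():
    """Recurrent-path experiment on a clean 3-subject cohort."""
    return run_rnn_experiment(seed=1)
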