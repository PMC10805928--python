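import numpy as np
import pytest

import metaconf as mc
from metaconf.simulate import records_to_frame


@pytest.fixture(scope="session")
def session_config():
    return mc.SessionConfig()


@pytest.fixture(scope="session")
def observer():
    return mc.ObserverParams()


@pytest.fixture(scope="session")
def single_session(session_config, observer):
    """One simulated participant (450 trials) as a trial table."""
    recs = mc.simulate_session(session_config, observer, "p001", seed=42)
    return records_to_frame(recs, session_config)


@pytest.fixture(scope="session")
def cohort(session_config, observer):
    """Six simulated participants with mild between-subject variation."""
    return mc.simulate_cohort(
        session_config, observer, cohort_size=6, seed=7, variation=mc.CohortVariation()
    )


def plain_sdt_counts(d, n, seed, n_bins=5, edges=(0.4, 0.8, 1.3, 2.0), criterion=0.0):
    """Type 2 counts from a plain equal-variance SDT observer whose
    confidence is a deterministic function of the decision variable.

    No staircase, no trial exclusion: the reference setting in which the
    meta-d' estimate must coincide with the type 1 d'.
    """
    rng = np.random.default_rng(seed)
    stim = rng.random(n) < 0.5  # True = class X
    x = rng.normal(np.where(stim, d / 2.0, -d / 2.0), 1.0)
    resp_x = x > criterion
    conf = np.searchsorted(np.asarray(edges), np.abs(x - criterion)) + 1
    conf = np.minimum(conf, n_bins)
    counts = np.zeros((2, 2 * n_bins))
    cell = np.where(resp_x, n_bins - 1 + conf, n_bins - conf)
    np.add.at(counts, (stim.astype(int), cell), 1)
    return mc.Type2Counts(n_bins, counts[0], counts[1]), stim, resp_x, conf
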