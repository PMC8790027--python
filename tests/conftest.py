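import numpy as np
import pandas as pd
import pytest

from s2mr import CohortConfig, RunConfig, generate_cohort


@pytest.fixture(scope="session")
def run_cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def small_bundles():
    """Three participants, one domain, 2 games x 3 questions."""
    cc = CohortConfig(n_participants=3, n_domains=1, n_games_per_domain=2,
                      n_questions_per_game=3, seed=42)
    return generate_cohort(cc, [])


@pytest.fixture(scope="session")
def one_bundle(small_bundles):
    return small_bundles[0]


def make_gaze(t, x, y, pupil=3.0, valid=None) -> pd.DataFrame:
    """Hand-built gaze frame for unit tests."""
    t = np.asarray(t, float)
    n = t.size
    x = np.broadcast_to(np.asarray(x, float), (n,)).copy()
    y = np.broadcast_to(np.asarray(y, float), (n,)).copy()
    p = np.broadcast_to(np.asarray(pupil, float), (n,)).copy()
    v = np.ones(n, int) if valid is None else np.asarray(valid, int)
    bad = v == 0
    x[bad] = np.nan
    y[bad] = np.nan
    pl, pr = p.copy(), p.copy()
    pl[bad] = np.nan
    pr[bad] = np.nan
    return pd.DataFrame(dict(t=t, x=x, y=y, pupil_l=pl, pupil_r=pr, valid=v))
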