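import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tachometric.design import TRIAL_COLUMNS

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_records(rpt, correct, congruency="congruent", soa_ms=0,
                 is_practice=False, participant="P01"):
    """Build a minimal trial table whose rPTs equal the given values.

    Gap is fixed at 0, so rt_ms = rpt + soa and rPT = rt - gap - soa
    reproduces ``rpt`` exactly.
    """
    rpt = np.asarray(rpt, dtype=float)
    correct = np.asarray(correct, dtype=float)
    n = len(rpt)
    df = pd.DataFrame({
        "participant": participant, "session": 1, "block": 1,
        "trial_in_block": np.arange(1, n + 1),
        "is_practice": is_practice,
        "congruency": congruency, "soa_ms": soa_ms, "gap_ms": 0,
        "fixation_ms": 400, "target": "left",
        "response": np.where(correct > 0, "left", "right"),
        "rt_ms": rpt + soa_ms, "correct": correct,
        "on_time": (rpt + soa_ms <= 1000).astype(float),
    })
    return df[TRIAL_COLUMNS]


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: no cross-test order dependence
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def exp1_nodip_trials():
    """A full-scale no-dip experiment (shared across tests: ~36k trials)."""
    from tachometric import load_preset, simulate_experiment
    spec, model = load_preset("exp1")
    return simulate_experiment(spec, model, seed=0)
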