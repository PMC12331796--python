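"""Type-I-error calibration of the minimum-vs-chance permutation test.

Under a pure guessing observer every trial's correctness is a fair coin, so
the test's null hypothesis is exactly true and its p-values should be
(sub)uniform: the rejection rate at level alpha, over many independently
simulated datasets, must not exceed alpha beyond Monte-Carlo noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .design import TRIAL_COLUMNS
from .inference import perm_test_min_vs_chance

__all__ = ["fair_coin_trials", "rejection_rate"]

_GAPS = (0, 100, 200, 300, 400, 500, 600, 700, 800, 900, 950)


def fair_coin_trials(n_trials: int, seed: int,
                     gap_levels_ms=_GAPS, rt_mean_ms: float = 800.0,
                     rt_sd_ms: float = 150.0, rt_min_ms: float = 100.0,
                     rt_max_ms: float = 1300.0) -> pd.DataFrame:
    """A dataset whose correctness is an independent fair coin per trial.

    Gaps cycle through the standard 11 urgency levels and RTs follow the
    same deadline-anchored truncated normal as the observer model, so the
    realized rPTs cover the analysis window the way real sessions do.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFA1C]))
    a = (rt_min_ms - rt_mean_ms) / rt_sd_ms
    b = (rt_max_ms - rt_mean_ms) / rt_sd_ms
    rt = np.round(stats.truncnorm.rvs(a, b, loc=rt_mean_ms, scale=rt_sd_ms,
                                      size=n_trials, random_state=rng))
    gaps = np.resize(np.asarray(gap_levels_ms), n_trials)
    correct = (rng.random(n_trials) < 0.5).astype(float)
    df = pd.DataFrame({
        "participant": "SIM", "session": 1, "block": 1,
        "trial_in_block": np.arange(1, n_trials + 1), "is_practice": False,
        "congruency": "incongruent", "soa_ms": 0, "gap_ms": gaps,
        "fixation_ms": 400, "target": "left",
        "response": np.where(correct > 0, "left", "right"),
        "rt_ms": rt, "correct": correct, "on_time": (rt <= 1000).astype(float),
    })
    return df[TRIAL_COLUMNS]


def rejection_rate(n_datasets: int = 200, n_trials: int = 2000,
                   n_perm: int = 400, alpha: float = 0.05,
                   seed: int = 0, span: float = 0.2, degree: int = 2) -> dict:
    """Fraction of fair-coin datasets on which the test rejects at alpha.

    Returns the rate together with the pieces needed to judge it: the
    rejection count, the number of datasets, and the 95% binomial
    confidence half-width around alpha for this many datasets.
    """
    n_reject = 0
    p_values = np.empty(n_datasets)
    for i in range(n_datasets):
        data = fair_coin_trials(n_trials, seed=1_000_003 * i + seed)
        res = perm_test_min_vs_chance(data, n_perm=n_perm,
                                      seed=2_000_003 * i + seed,
                                      span=span, degree=degree)
        p_values[i] = res.p_value
        n_reject += res.p_value <= alpha
    half = 1.96 * np.sqrt(alpha * (1 - alpha) / n_datasets)
    return {"rate": n_reject / n_datasets, "n_reject": int(n_reject),
            "n_datasets": n_datasets, "n_trials": n_trials, "n_perm": n_perm,
            "alpha": alpha, "binomial_ci_half_width": float(half),
            "p_values": p_values}
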