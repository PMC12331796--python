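"""Parametric observer for simulating accuracy as a function of processing time.

The generative law mirrors the canonical shape of a tachometric function:
guessing-level accuracy at short (or negative) raw processing times, a
logistic rise towards a near-perfect asymptote, an additive rightward shift
of the rise on incongruent trials (the flanker effect), and -- only when the
flankers lead the target (SOA > 0) and conflict with it -- a Gaussian
below-chance dip caused by responses driven by the prematurely available
flanker information. An optional linear late decline models the slight drop
in accuracy at very long processing times.

Response times are drawn from a deadline-anchored truncated normal,
independent of the gap, so that realized rPT = RT - gap - SOA spans the
analysis window across all gap levels.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .design import DesignSpec, build_design

__all__ = ["ObserverModel", "p_correct", "simulate_trials", "calibrate_dip_depth"]


@dataclass(frozen=True)
class ObserverModel:
    """Generative parameters for accuracy-vs-rPT behavior.

    All durations are in milliseconds; probabilities in [0, 1].

    Attributes
    ----------
    p_floor
        Guessing accuracy at uninformative rPTs (nominally 0.5).
    hand_bias
        Probability of choosing the right-hand response when guessing
        (0.5 = unbiased).
    p_asym
        Asymptotic accuracy at long rPTs.
    rise_mid_ms, rise_scale_ms
        Location (half-rise) and steepness scale of the logistic rise.
    congruency_delay_ms
        Additive shift of the rise midpoint on incongruent trials.
    dip_depth, dip_center_ms, dip_width_ms
        Amplitude, center and SD of the Gaussian below-chance dip, applied
        on incongruent trials only.
    dip_soa_gated
        When true, the dip additionally requires SOA > 0, i.e. it only
        materializes when the flankers lead the target (the processing
        asymmetry that the SOA manipulation creates artificially).
    late_decline_per_ms, late_decline_onset_ms
        Linear accuracy loss per ms beyond the onset (default off).
    rt_mean_ms, rt_sd_ms, rt_min_ms, rt_max_ms
        Truncated-normal response-time distribution from the Go-signal.
    guess_threshold_ms
        rPTs below this are pre-stimulus: the response is a (possibly
        hand-biased) guess rather than a draw from the accuracy curve.
    """

    p_floor: float = 0.5
    hand_bias: float = 0.5
    p_asym: float = 0.97
    rise_mid_ms: float = 250.0
    rise_scale_ms: float = 40.0
    congruency_delay_ms: float = 50.0
    dip_depth: float = 0.0
    dip_center_ms: float = 400.0
    dip_width_ms: float = 80.0
    dip_soa_gated: bool = False
    late_decline_per_ms: float = 0.0
    late_decline_onset_ms: float = 800.0
    rt_mean_ms: float = 800.0
    rt_sd_ms: float = 150.0
    rt_min_ms: float = 100.0
    rt_max_ms: float = 1300.0
    guess_threshold_ms: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_floor <= self.p_asym <= 1.0):
            raise ValueError("need 0 <= p_floor <= p_asym <= 1")
        if self.dip_depth < 0:
            raise ValueError("dip_depth must be >= 0")
        if not (self.rt_min_ms < self.rt_max_ms):
            raise ValueError("rt_min_ms must be below rt_max_ms")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverModel":
        return cls(**d)


# evaluated probabilities are kept off the exact 0/1 boundary
_P_CLIP = (0.001, 0.999)


def p_correct(model: ObserverModel, rpt_ms, congruency, soa_ms=0.0) -> np.ndarray:
    """Probability of a correct response at a given raw processing time.

    ``congruency`` is ``"congruent"``/``"incongruent"`` (scalar or array);
    ``soa_ms`` matters only for SOA-gated dips, where the flanker-driven
    below-chance episode requires the flankers to lead the target.
    Deterministic and vectorized.
    """
    rpt = np.asarray(rpt_ms, dtype=float)
    incong = np.asarray(congruency) == "incongruent"
    soa = np.asarray(soa_ms, dtype=float)
    delay = np.where(incong, model.congruency_delay_ms, 0.0)
    rise = special.expit((rpt - model.rise_mid_ms - delay) / model.rise_scale_ms)
    p = model.p_floor + (model.p_asym - model.p_floor) * rise
    if model.dip_depth > 0:
        bump = np.exp(-0.5 * ((rpt - model.dip_center_ms) / model.dip_width_ms) ** 2)
        active = incong & (soa > 0) if model.dip_soa_gated else incong
        p = p - model.dip_depth * bump * active
    if model.late_decline_per_ms > 0:
        p = p - model.late_decline_per_ms * np.maximum(0.0, rpt - model.late_decline_onset_ms)
    return np.clip(p, *_P_CLIP)


def calibrate_dip_depth(model: ObserverModel, target_min: float,
                        restriction_ms: float = 0.0,
                        grid_max_ms: float = 1000.0) -> ObserverModel:
    """Return a copy of ``model`` with ``dip_depth`` set so the generative
    incongruent (SOA > 0) curve attains ``target_min`` over rPT > restriction.

    Solved by bisection on the restricted minimum of :func:`p_correct`,
    which decreases monotonically in ``dip_depth``.
    """
    grid = np.arange(np.floor(restriction_ms) + 1, grid_max_ms + 1)

    def restricted_min(depth: float) -> float:
        m = ObserverModel(**{**model.to_dict(), "dip_depth": depth})
        return float(p_correct(m, grid, "incongruent", soa_ms=120.0).min())

    if restricted_min(0.0) < target_min:
        raise ValueError("curve already below target_min with no dip")
    depth = optimize.brentq(lambda d: restricted_min(d) - target_min, 0.0, 1.5,
                            xtol=1e-10)
    return ObserverModel(**{**model.to_dict(), "dip_depth": float(depth)})


def simulate_trials(design: pd.DataFrame, model: ObserverModel, seed: int,
                    deadline_ms: float = 1000.0) -> pd.DataFrame:
    """Fill a design skeleton with simulated responses.

    RTs (from the Go-signal) are truncated-normal, independent of gap, and
    rounded to integer milliseconds as a response device would record them.
    Correctness is Bernoulli in the observer's accuracy curve evaluated at
    the trial's realized rPT; pre-stimulus responses (rPT below the guessing
    threshold) instead follow the hand-biased guessing rule, so their
    accuracy derives from the balanced left/right target assignment.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51D3]))
    out = design.copy()
    n = len(out)
    a = (model.rt_min_ms - model.rt_mean_ms) / model.rt_sd_ms
    b = (model.rt_max_ms - model.rt_mean_ms) / model.rt_sd_ms
    rt = stats.truncnorm.rvs(a, b, loc=model.rt_mean_ms, scale=model.rt_sd_ms,
                             size=n, random_state=rng)
    rt = np.round(rt)
    gap = out["gap_ms"].to_numpy(dtype=float)
    soa = out["soa_ms"].to_numpy(dtype=float)
    rpt = rt - gap - soa
    guessing = rpt < model.guess_threshold_ms

    targets = out["target"].to_numpy()
    response = np.empty(n, dtype=object)
    # guessed responses: choose "right" with probability hand_bias
    pick_right = rng.random(n) < model.hand_bias
    response[guessing] = np.where(pick_right[guessing], "right", "left")
    correct = np.empty(n, dtype=float)
    correct[guessing] = (response[guessing] == targets[guessing]).astype(float)

    driven = ~guessing
    p = p_correct(model, rpt[driven], out["congruency"].to_numpy()[driven],
                  soa_ms=soa[driven])
    hit = rng.random(driven.sum()) < p
    correct[driven] = hit.astype(float)
    other = np.where(targets == "left", "right", "left")
    response[driven] = np.where(hit, targets[driven], other[driven])

    out["rt_ms"] = rt
    out["response"] = response
    out["correct"] = correct
    out["on_time"] = (rt <= deadline_ms).astype(float)
    return out


def simulate_experiment(spec: DesignSpec, model: ObserverModel, seed: int) -> pd.DataFrame:
    """Convenience wrapper: build the design and simulate it with one seed."""
    design = build_design(spec, seed)
    return simulate_trials(design, model, seed, deadline_ms=spec.deadline_ms)
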