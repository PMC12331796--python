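"""Nonparametric inference on tachometric curves.

The scientific question is whether accuracy on incongruent trials *drops
below chance* in some processing-time window (stimulus-driven responding),
and whether that drop is deeper than on congruent trials. All inference is
nonparametric and runs the full estimation pipeline (bin -> smooth ->
restricted minimum) inside each resampling replicate:

* restricted curve minima (rPT > 0 only, since negative-rPT responses are
  pre-stimulus guesses and their minima are uninformative);
* a permutation test on the difference of two conditions' minima, with
  condition labels randomly reassigned over the pooled trials;
* a permutation test of one condition's minimum against chance, with
  correctness regenerated as a fair coin while every trial keeps its rPT;
* bootstrap standard errors of the minimum (trials resampled with
  replacement);
* the 1.96 * sqrt(p0(1-p0)/n) binomial confidence band around chance; and
* per-100-ms-bin Bayes factors for below-chance and above-chance accuracy
  against the point null p = 0.5, under a one-side-truncated logistic prior
  on the log-odds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats

from .curves import (EstimationError, RPT_WINDOW, TachometricCurve,
                     bin_accuracy, filter_trials, loess_operator,
                     loess_values, rpt_grid)

__all__ = [
    "MinimumStat", "PermutationResult", "ChanceBand",
    "curve_minimum", "perm_test_min_diff", "perm_test_min_vs_chance",
    "bootstrap_min_se", "chance_band", "band_exceedance", "bayes_factors",
]


# --------------------------------------------------------------------------
# minima
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MinimumStat:
    """Minimum of a smoothed curve over rPT strictly above ``restriction_ms``."""

    min_value: float
    argmin_rpt_ms: float
    restriction_ms: float = 0.0


def curve_minimum(curve: TachometricCurve, restriction_ms: float = 0.0) -> MinimumStat:
    """Restricted minimum of the smoothed curve; ties go to the smallest rPT."""
    mask = curve.grid_ms > restriction_ms
    if not mask.any():
        raise ValueError("no grid points above the restriction")
    vals = curve.p_smooth[mask]
    i = int(np.argmin(vals))           # first occurrence = smallest rPT
    return MinimumStat(float(vals[i]), float(curve.grid_ms[mask][i]),
                       float(restriction_ms))


def _prep_arrays(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Filter a trial table and reduce it to (bin index, correctness) arrays."""
    filtered, _ = filter_trials(records)
    if filtered.empty:
        raise ValueError("no analyzable trials after filtering")
    grid0 = rpt_grid()[0]
    idx = np.rint(filtered["rpt_ms"].to_numpy(dtype=float)).astype(int) - grid0
    corr = filtered["correct"].to_numpy(dtype=float)
    return idx, corr


def _restricted_min(idx: np.ndarray, corr: np.ndarray, span: float,
                    degree: int, restriction_ms: float,
                    count_weighted: bool = False) -> float:
    """bin -> smooth -> restricted minimum on raw (bin index, correct) arrays."""
    grid = rpt_grid()
    n_b = np.bincount(idx, minlength=grid.size)
    k_b = np.bincount(idx, weights=corr, minlength=grid.size)
    nz = n_b > 0
    centers = grid[nz].astype(float)
    # local fits at distinct grid points are independent, so evaluating only
    # the restricted part of the grid yields the same minimum
    eval_grid = grid[grid > restriction_ms].astype(float)
    p = np.clip(loess_values(centers, k_b[nz] / n_b[nz], span=span,
                             degree=degree, grid=eval_grid,
                             counts=n_b[nz].astype(float),
                             count_weighted=count_weighted), 0.0, 1.0)
    return float(p.min())


# --------------------------------------------------------------------------
# permutation tests
# --------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed: float
    null_draws: np.ndarray
    n_permutations: int
    p_value: float
    sidedness: str                # "two-sided" | "lower" | "upper"
    seed: int | None = None
    n_redrawn: int = 0            # degenerate replicates that were redrawn
    exhaustive: bool = False


_TIE_TOL = 1e-12   # |null| >= |obs| comparisons are tolerant to float noise


def perm_test_min_diff(records_a: pd.DataFrame, records_b: pd.DataFrame,
                       n_perm: int = 1000, seed: int = 0, span: float = 0.2,
                       degree: int = 2, restriction_ms: float = 0.0,
                       exhaustive: bool = False,
                       count_weighted: bool = False) -> PermutationResult:
    """Permutation test on the difference of two conditions' curve minima.

    The observed statistic is ``min_a - min_b`` (each condition run through
    the full bin -> smooth -> restricted-minimum pipeline). Under the null,
    condition labels are exchangeable: trials are pooled and randomly
    relabelled preserving the two group sizes, and the statistic recomputed
    per replicate. Two-sided p with the add-one correction,
    ``p = (1 + #{|null| >= |observed|}) / (1 + n_perm)``.

    With ``exhaustive=True`` every distinct relabelling is enumerated
    (feasible only for toy inputs) and p is the exact fraction of
    relabellings — the identity included — at least as extreme as observed.

    Replicates in which a group ends up with too few nonempty bins to
    smooth are discarded and redrawn; the count is reported.
    """
    idx_a, corr_a = _prep_arrays(records_a)
    idx_b, corr_b = _prep_arrays(records_b)
    args = (span, degree, restriction_ms, count_weighted)
    observed = _restricted_min(idx_a, corr_a, *args) \
        - _restricted_min(idx_b, corr_b, *args)

    idx = np.concatenate([idx_a, idx_b])
    corr = np.concatenate([corr_a, corr_b])
    n_a, n_tot = idx_a.size, idx.size

    if exhaustive:
        null = []
        for pick in combinations(range(n_tot), n_a):
            sel = np.zeros(n_tot, dtype=bool)
            sel[list(pick)] = True
            stat = _restricted_min(idx[sel], corr[sel], *args) \
                - _restricted_min(idx[~sel], corr[~sel], *args)
            null.append(stat)
        null = np.asarray(null)
        p = float(np.mean(np.abs(null) >= np.abs(observed) - _TIE_TOL))
        return PermutationResult(observed, null, null.size, p, "two-sided",
                                 seed=None, exhaustive=True)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA1B2]))
    null = np.empty(n_perm)
    redrawn = 0
    got = 0
    while got < n_perm:
        perm = rng.permutation(n_tot)
        sel, rest = perm[:n_a], perm[n_a:]
        try:
            null[got] = _restricted_min(idx[sel], corr[sel], *args) \
                - _restricted_min(idx[rest], corr[rest], *args)
        except EstimationError:
            redrawn += 1
            if redrawn > 100 * n_perm:
                raise
            continue
        got += 1
    exceed = int(np.sum(np.abs(null) >= np.abs(observed) - _TIE_TOL))
    p = (1 + exceed) / (1 + n_perm)
    return PermutationResult(observed, null, n_perm, p, "two-sided",
                             seed=int(seed), n_redrawn=redrawn)


def perm_test_min_vs_chance(records: pd.DataFrame, n_perm: int = 1000,
                            seed: int = 0, span: float = 0.2, degree: int = 2,
                            restriction_ms: float = 0.0, p0: float = 0.5,
                            count_weighted: bool = False) -> PermutationResult:
    """Test one condition's restricted curve minimum against chance.

    Null model: every trial keeps its rPT, but its correctness is
    regenerated as an independent fair coin (Bernoulli ``p0``); the full
    pipeline is recomputed per replicate. Lower-sided p (evidence that the
    minimum is *below* what guessing produces),
    ``p = (1 + #{null <= observed}) / (1 + n_perm)``.

    Because the rPTs — and hence the bin occupancy and the smoothing
    operator — are identical in every replicate, the per-replicate pipeline
    reduces exactly to the fixed hat matrix applied to the regenerated
    per-bin proportions, which is how it is computed.
    """
    idx, corr = _prep_arrays(records)
    grid = rpt_grid()
    n_b = np.bincount(idx, minlength=grid.size)
    nz = n_b > 0
    centers = grid[nz].astype(float)
    counts = n_b[nz].astype(float)
    L, _ = loess_operator(centers, span=span, degree=degree, counts=counts,
                          count_weighted=count_weighted)
    k_obs = np.bincount(idx, weights=corr, minlength=grid.size)[nz]
    lo = grid > restriction_ms
    observed = float(np.clip(L @ (k_obs / counts), 0.0, 1.0)[lo].min())

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC41C]))
    k_null = rng.binomial(counts.astype(int)[:, None], p0,
                          size=(counts.size, n_perm))
    p_null = np.clip(L @ (k_null / counts[:, None]), 0.0, 1.0)
    null = p_null[lo].min(axis=0)
    exceed = int(np.sum(null <= observed + _TIE_TOL))
    p = (1 + exceed) / (1 + n_perm)
    return PermutationResult(observed, null, n_perm, p, "lower", seed=int(seed))


def bootstrap_min_se(records: pd.DataFrame, n_boot: int = 1000, seed: int = 0,
                     span: float = 0.2, degree: int = 2,
                     restriction_ms: float = 0.0,
                     count_weighted: bool = False) -> float:
    """Bootstrap standard error of the restricted curve minimum.

    Trials are resampled with replacement within the condition; each
    resample is run through the full pipeline. Resamples that leave too few
    nonempty bins to smooth are redrawn.
    """
    idx, corr = _prep_arrays(records)
    n = idx.size
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB007]))
    args = (span, degree, restriction_ms, count_weighted)
    mins = np.empty(n_boot)
    got = 0
    redrawn = 0
    while got < n_boot:
        take = rng.integers(0, n, size=n)
        try:
            mins[got] = _restricted_min(idx[take], corr[take], *args)
        except EstimationError:
            redrawn += 1
            if redrawn > 100 * n_boot:
                raise
            continue
        got += 1
    return float(np.std(mins, ddof=1))


# --------------------------------------------------------------------------
# chance band
# --------------------------------------------------------------------------

@dataclass
class ChanceBand:
    """Binomial confidence band around chance: p0 +/- z*sqrt(p0(1-p0)/n)."""

    p0: float
    z: float
    half_width: np.ndarray    # NaN where the local trial count is zero
    grid_ms: np.ndarray

    @property
    def lower(self) -> np.ndarray:
        return self.p0 - self.half_width

    @property
    def upper(self) -> np.ndarray:
        return self.p0 + self.half_width


def chance_band(curve: TachometricCurve, p0: float = 0.5,
                z: float = 1.96) -> ChanceBand:
    """Band half-width per grid point, from the local trial count backing
    the smoothed estimate there (``z * sqrt(p0 (1 - p0) / n_local)``)."""
    n = curve.n_local.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        hw = np.where(n > 0, z * np.sqrt(p0 * (1 - p0) / n), np.nan)
    return ChanceBand(p0=p0, z=z, half_width=hw, grid_ms=curve.grid_ms)


def band_exceedance(curve: TachometricCurve, band: ChanceBand,
                    restriction_ms: float | None = None) -> dict:
    """First/last grid ms at which the curve leaves the band, each side.

    Returns ``{"below": (first, last) | None, "above": (first, last) | None}``;
    optionally only grid points with rPT above ``restriction_ms`` count.
    """
    ok = np.isfinite(band.half_width)
    if restriction_ms is not None:
        ok &= curve.grid_ms > restriction_ms
    out = {}
    for side, hit in (("below", curve.p_smooth < band.lower),
                      ("above", curve.p_smooth > band.upper)):
        w = np.where(hit & ok)[0]
        out[side] = (int(curve.grid_ms[w[0]]), int(curve.grid_ms[w[-1]])) \
            if w.size else None
    return out


def classify_dip(curve: TachometricCurve, band: ChanceBand,
                 restriction_ms: float = 0.0, min_run_ms: int = 50,
                 clearance: float = 1.0) -> tuple[bool, tuple[int, int] | None]:
    """Does the curve drop *meaningfully* below chance?

    A dip is a run of at least ``min_run_ms`` consecutive grid points above
    the rPT restriction at which the smoothed curve lies below the band's
    lower limit, reaching — somewhere within the run — at least
    ``clearance`` band half-widths *below* that limit. Both requirements
    target sampling noise: isolated crossings are short, and smoothing
    correlation can stretch a marginal wander past any duration cutoff, but
    neither produces a deep excursion, whereas the stimulus-driven
    below-chance episode is both sustained and clearly outside the band.
    Returns the flag and the deepest qualifying run (first, last grid ms);
    when no run qualifies, the longest below-band run is still reported.
    """
    ok = np.isfinite(band.half_width) & (curve.grid_ms > restriction_ms)
    hit = (curve.p_smooth < band.lower) & ok
    best = None
    best_len = 0
    found = False
    i = 0
    while i < hit.size:
        if hit[i]:
            j = i
            while j + 1 < hit.size and hit[j + 1]:
                j += 1
            sl = slice(i, j + 1)
            depth = band.lower[sl] - curve.p_smooth[sl]
            deep = bool(np.any(depth >= clearance * band.half_width[sl]))
            qualifies = (j - i + 1 >= min_run_ms) and deep
            if qualifies and not found:
                best, best_len, found = None, 0, True
            if qualifies == found and j - i + 1 > best_len:
                best_len = j - i + 1
                best = (int(curve.grid_ms[i]), int(curve.grid_ms[j]))
            i = j + 1
        else:
            i += 1
    return found, best


# --------------------------------------------------------------------------
# Bayes factors
# --------------------------------------------------------------------------

def _log_bf_one_sided(k: int, n: int, side: str, prior_scale: float,
                      p0: float = 0.5) -> float:
    """Natural-log Bayes factor for the one-sided proportion model.

    H1 puts a logistic prior (location logit(p0), scale ``prior_scale``)
    on the log-odds, truncated to omega > 0 ("above") or omega < 0
    ("below"); H0 is the point null p = p0. The marginal likelihood ratio

        BF = int  L(k, n | p(omega)) / L(k, n | p0) * prior(omega) d omega

    is computed by adaptive quadrature in a numerically shifted scale, so
    that very large factors (e.g. k = n at large n) stay finite in log space.
    """
    lo0 = special.logit(p0)

    def log_ratio(om: np.ndarray) -> np.ndarray:
        # log L(p(omega)) - log L(p0), stable for large |omega|
        lp = -np.logaddexp(0.0, -(om + lo0))       # log p
        lq = -np.logaddexp(0.0, om + lo0)          # log (1 - p)
        return k * (lp - np.log(p0)) + (n - k) * (lq - np.log1p(-p0))

    sgn = 1.0 if side == "above" else -1.0

    def g(t: np.ndarray) -> np.ndarray:
        om = sgn * t
        # truncated logistic prior: pdf doubled on the kept half-line
        logprior = np.log(2.0) + stats.logistic.logpdf(om, loc=0.0,
                                                       scale=prior_scale)
        return log_ratio(om) + logprior

    # locate the integrand's peak, then pick an upper limit where the
    # log-integrand has dropped far below it
    t_grid = np.linspace(1e-9, 60.0 * prior_scale, 4001)
    gv = g(t_grid)
    m = float(gv.max())
    t_peak = float(t_grid[int(np.argmax(gv))])
    beyond = np.where((t_grid > t_peak) & (gv < m - 60.0))[0]
    upper = float(t_grid[beyond[0]]) if beyond.size else float(t_grid[-1])

    val, _ = integrate.quad(lambda t: np.exp(g(t) - m), 0.0, upper,
                            points=[t_peak], limit=200)
    if val <= 0.0:
        return -np.inf
    return m + float(np.log(val))


def bayes_factors(records: pd.DataFrame, bin_width_ms: int = 100,
                  prior_scale: float = 0.5, p0: float = 0.5) -> pd.DataFrame:
    """Per-time-bin Bayes factors for below- and above-chance accuracy.

    The rPT window is partitioned into ``bin_width_ms`` bins; within each,
    the trial count n and correct count k feed two one-sided Bayes factors
    against the point null p = 0.5 (below vs identical; above vs identical).
    Reported as decadal logarithms; ±inf and empty-bin sentinels retained.
    """
    lo, hi = RPT_WINDOW
    if (hi - lo) % bin_width_ms != 0:
        raise ValueError("bin width must partition the rPT window")
    filtered, _ = filter_trials(records)
    edges = np.arange(lo, hi + 1, bin_width_ms)
    rpt = filtered["rpt_ms"].to_numpy(dtype=float)
    corr = filtered["correct"].to_numpy(dtype=float)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        # half-open bins, final bin closed, so bins partition the window
        inb = (rpt >= a) & ((rpt < b) if b < hi else (rpt <= b))
        n, k = int(inb.sum()), int(corr[inb].sum())
        if n == 0:
            below = above = np.nan
        else:
            below = _log_bf_one_sided(k, n, "below", prior_scale, p0) / np.log(10)
            above = _log_bf_one_sided(k, n, "above", prior_scale, p0) / np.log(10)
        rows.append({"bin_start_ms": int(a), "bin_end_ms": int(b),
                     "n": n, "k": k,
                     "log10_bf_below": below, "log10_bf_above": above})
    return pd.DataFrame(rows)
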