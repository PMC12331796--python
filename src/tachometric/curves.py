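"""Tachometric-curve estimation: rPT, trial filtering, binning, smoothing.

The tachometric function is the probability of a correct response as a
function of the raw processing time

    rPT = RT - gap  (minus the SOA when the flankers lead the target),

i.e. the time the target was actually visible before the response. Analysis
proceeds in two steps, on the aggregated trial table: the proportion correct
is computed in non-overlapping 1-ms bins over the window [-200, 1000] ms,
and those binned proportions are then locally regressed (tricube-weighted
local polynomial with a nearest-neighbour span bandwidth, default span 0.2,
degree 2) onto the full 1-ms grid.

The smoother is linear in the binned proportions; :func:`loess_operator`
exposes the underlying hat matrix, which the resampling tests in
:mod:`tachometric.inference` reuse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RPT_WINDOW", "rpt_grid", "compute_rpt", "add_rpt", "filter_trials",
    "bin_accuracy", "smooth_curve", "loess_operator", "TachometricCurve",
    "EstimationError",
]

#: Closed rPT analysis window in ms.
RPT_WINDOW = (-200, 1000)


class EstimationError(ValueError):
    """Raised when a curve cannot be estimated (e.g. too few nonempty bins)."""


def rpt_grid() -> np.ndarray:
    """The 1-ms evaluation grid, -200..1000 inclusive."""
    return np.arange(RPT_WINDOW[0], RPT_WINDOW[1] + 1)


def compute_rpt(rt_ms, gap_ms, soa_ms=0.0):
    """rPT = RT - gap - SOA (all in ms from the Go-signal)."""
    return np.asarray(rt_ms, dtype=float) - np.asarray(gap_ms, dtype=float) \
        - np.asarray(soa_ms, dtype=float)


def add_rpt(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with an ``rpt_ms`` column computed per trial."""
    out = records.copy()
    soa = out["soa_ms"] if "soa_ms" in out else 0.0
    out["rpt_ms"] = compute_rpt(out["rt_ms"], out["gap_ms"], soa)
    return out


def filter_trials(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the analysis exclusions, preserving order.

    Drops practice trials, then trials outside the closed rPT window
    [-200, 1000] ms (negative rPTs down to -200 are retained: they are
    pre-stimulus guesses but still carry the chance baseline; rPTs above
    1,000 ms lie outside the response deadline even at gap 0). Returns the
    retained table and an accounting dict with one count per exclusion rule.
    """
    recs = records if "rpt_ms" in records.columns else add_rpt(records)
    counts = {"n_input": len(recs)}
    practice = recs["is_practice"].astype(bool) if "is_practice" in recs else \
        pd.Series(False, index=recs.index)
    counts["n_practice_excluded"] = int(practice.sum())
    recs = recs.loc[~practice]
    lo, hi = RPT_WINDOW
    below = recs["rpt_ms"] < lo
    above = recs["rpt_ms"] > hi
    counts["n_below_window"] = int(below.sum())
    counts["n_above_window"] = int(above.sum())
    recs = recs.loc[~(below | above)]
    counts["n_retained"] = len(recs)
    return recs, counts


def bin_accuracy(records: pd.DataFrame) -> pd.DataFrame:
    """Proportion correct per 1-ms rPT bin over the full analysis grid.

    Trials are assigned to the nearest integer millisecond. Every grid value
    gets a row; bins without trials have ``n_trials = 0`` and ``p_hat`` NaN,
    and are dropped before smoothing (an empty bin carries no information).
    """
    grid = rpt_grid()
    out = pd.DataFrame({"rpt_bin_ms": grid, "n_trials": 0, "n_correct": 0})
    if len(records):
        bins = np.rint(records["rpt_ms"].to_numpy(dtype=float)).astype(int)
        if bins.min() < grid[0] or bins.max() > grid[-1]:
            raise ValueError("records outside the rPT window; run filter_trials first")
        idx = bins - grid[0]
        out["n_trials"] = np.bincount(idx, minlength=len(grid))
        out["n_correct"] = np.bincount(
            idx, weights=records["correct"].to_numpy(dtype=float),
            minlength=len(grid)).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["p_hat"] = np.where(out["n_trials"] > 0,
                                out["n_correct"] / out["n_trials"], np.nan)
    return out


@dataclass
class TachometricCurve:
    """A smoothed tachometric function on the 1-ms grid."""

    grid_ms: np.ndarray
    p_smooth: np.ndarray
    n_local: np.ndarray          # trials inside each grid point's bandwidth
    n_trials_bin: np.ndarray     # raw per-bin trial counts (incl. empty bins)
    condition: str = ""
    span: float = 0.2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition": self.condition, "rpt_ms": self.grid_ms,
            "p_smooth": self.p_smooth, "n_local": self.n_local,
            "n_trials_bin": self.n_trials_bin,
        })


def _loess_weights(centers: np.ndarray, grid: np.ndarray, span: float,
                   degree: int, counts, count_weighted: bool):
    """Signed offsets, tricube weights and bandwidths for every grid point."""
    n = centers.size
    q = max(int(np.floor(span * n)), degree + 2)
    if q > n:
        raise EstimationError(
            f"too few nonempty bins for smoothing (have {n}, span {span})")
    d = grid[:, None] - centers[None, :]
    ad = np.abs(d)
    h = np.partition(ad, q - 1, axis=1)[:, q - 1]
    h = np.maximum(h, 1e-12)
    u = ad / h[:, None]
    w = np.clip(1.0 - u ** 3, 0.0, None)
    w *= w * w
    if count_weighted:
        if counts is None:
            raise ValueError("count_weighted smoothing requires counts")
        w = w * np.asarray(counts, dtype=float)
    return d, w, h


def _moment_matrix(d: np.ndarray, w: np.ndarray, degree: int) -> np.ndarray:
    """Per-grid-point normal-equation matrices M[i, j] = sum w * d^(i+j)."""
    n_grid = d.shape[0]
    S = np.empty((2 * degree + 1, n_grid))
    acc = w.copy()
    S[0] = acc.sum(axis=1)
    for k in range(1, 2 * degree + 1):
        acc *= d
        S[k] = acc.sum(axis=1)
    M = np.empty((n_grid, degree + 1, degree + 1))
    for i in range(degree + 1):
        for j in range(degree + 1):
            M[:, i, j] = S[i + j]
    return M


def loess_values(centers: np.ndarray, y: np.ndarray, span: float = 0.2,
                 degree: int = 2, grid: np.ndarray | None = None,
                 counts: np.ndarray | None = None,
                 count_weighted: bool = False) -> np.ndarray:
    """Local polynomial fit evaluated on the grid, without forming the hat
    matrix — algebraically identical to ``loess_operator(...) @ y`` but
    cheaper, which matters inside resampling loops."""
    centers = np.asarray(centers, dtype=float)
    if grid is None:
        grid = rpt_grid()
    grid = np.asarray(grid, dtype=float)
    d, w, _ = _loess_weights(centers, grid, span, degree, counts, count_weighted)
    M = _moment_matrix(d, w, degree)
    T = np.empty((grid.size, degree + 1))
    acc = w * np.asarray(y, dtype=float)
    T[:, 0] = acc.sum(axis=1)
    for k in range(1, degree + 1):
        acc *= d
        T[:, k] = acc.sum(axis=1)
    try:
        beta = np.linalg.solve(M, T[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.stack([np.linalg.lstsq(Mi, Ti, rcond=None)[0]
                         for Mi, Ti in zip(M, T)])
    return beta[:, 0]


def loess_operator(centers: np.ndarray, span: float = 0.2, degree: int = 2,
                   grid: np.ndarray | None = None,
                   counts: np.ndarray | None = None,
                   count_weighted: bool = False):
    """Linear smoothing operator of a local polynomial regression.

    Parameters
    ----------
    centers
        Predictor values of the nonempty bins (strictly increasing).
    span
        Fraction of bins inside each local neighbourhood (nearest-neighbour
        bandwidth); the local window at grid point ``x0`` reaches to its
        q-th nearest bin, ``q = max(floor(span * n_bins), degree + 2)``.
    degree
        Local polynomial degree (2 reproduces the conventional default of
        the R procedure this smoother follows).
    counts
        Per-bin trial counts; needed for ``n_local`` and count weighting.
    count_weighted
        Multiply the tricube kernel by the bin counts (optional mode; the
        default regression treats all nonempty bins equally).

    Returns
    -------
    L : (n_grid, n_bins) ndarray
        Hat matrix: ``p_smooth = L @ p_hat`` (before clipping to [0, 1]).
    n_local : (n_grid,) ndarray
        Trials within each grid point's bandwidth window (zeros if
        ``counts`` is None).
    """
    centers = np.asarray(centers, dtype=float)
    if grid is None:
        grid = rpt_grid()
    grid = np.asarray(grid, dtype=float)
    d, w, h = _loess_weights(centers, grid, span, degree, counts, count_weighted)
    M = _moment_matrix(d, w, degree)
    e0 = np.zeros(degree + 1)
    e0[0] = 1.0
    rhs = np.broadcast_to(e0[:, None], (grid.size, degree + 1, 1))
    try:
        a = np.linalg.solve(M, rhs)[..., 0]
    except np.linalg.LinAlgError:
        a = np.stack([np.linalg.lstsq(Mi, e0, rcond=None)[0] for Mi in M])
    # hat row = sum_j a_j * w * d^j, built without a (degree+1, grid, bins) tensor
    L = a[:, 0, None] * w
    acc = w
    for j in range(1, degree + 1):
        acc = acc * d
        L += a[:, j, None] * acc

    if counts is not None:
        inside = np.abs(d) <= h[:, None] + 1e-12
        n_local = inside @ np.asarray(counts, dtype=float)
    else:
        n_local = np.zeros(grid.size)
    return L, n_local


def smooth_curve(bins: pd.DataFrame, span: float = 0.2, condition: str = "",
                 degree: int = 2, count_weighted: bool = False) -> TachometricCurve:
    """Locally regress binned accuracy onto the 1-ms grid.

    ``bins`` is the output of :func:`bin_accuracy`. Empty bins are dropped
    before the regression; the fitted curve is clipped to [0, 1]. Requires
    at least ``max(10, ceil(2/span))`` nonempty bins.
    """
    nonempty = bins.loc[bins["n_trials"] > 0]
    if len(nonempty) < max(10, int(np.ceil(2.0 / span))):
        raise EstimationError(
            f"too few nonempty bins for a curve (have {len(nonempty)}, span {span})")
    centers = nonempty["rpt_bin_ms"].to_numpy(dtype=float)
    counts = nonempty["n_trials"].to_numpy(dtype=float)
    y = nonempty["p_hat"].to_numpy(dtype=float)
    L, n_local = loess_operator(centers, span=span, degree=degree,
                                counts=counts, count_weighted=count_weighted)
    p = np.clip(L @ y, 0.0, 1.0)
    full = bins.set_index("rpt_bin_ms").reindex(rpt_grid())
    return TachometricCurve(
        grid_ms=rpt_grid(), p_smooth=p, n_local=n_local,
        n_trials_bin=full["n_trials"].fillna(0).to_numpy(dtype=int),
        condition=condition, span=span)


def curve_from_records(records: pd.DataFrame, span: float = 0.2,
                       condition: str = "", degree: int = 2,
                       count_weighted: bool = False) -> TachometricCurve:
    """filter -> bin -> smooth convenience chain for one condition's trials."""
    filtered, _ = filter_trials(records)
    return smooth_curve(bin_accuracy(filtered), span=span, condition=condition,
                        degree=degree, count_weighted=count_weighted)
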