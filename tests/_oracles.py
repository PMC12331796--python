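"""Independent brute-force oracles used only by the test suite.

Each oracle is written from the mathematical definition, deliberately not
sharing code with the package: per-grid-point weighted least squares for
the local regression, exhaustive relabelling enumeration for the
permutation test, and dense trapezoid quadrature for the proportion Bayes
factors.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.special import expit
from scipy.stats import logistic


def loess_wls(centers, y, grid, span=0.2, degree=2):
    """Local polynomial regression by explicit WLS at every grid point."""
    centers = np.asarray(centers, float)
    y = np.asarray(y, float)
    n = len(centers)
    q = max(int(np.floor(span * n)), degree + 2)
    out = np.empty(len(grid))
    for i, x0 in enumerate(np.asarray(grid, float)):
        d = np.abs(centers - x0)
        h = max(np.sort(d)[q - 1], 1e-12)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        X = np.vander(centers - x0, degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(sw[:, None] * X, sw * y, rcond=None)
        out[i] = beta[0]
    return out


def restricted_min_wls(rpt, correct, span=0.2, degree=2, restriction=0.0,
                       grid_lo=-200, grid_hi=1000):
    """bin -> WLS-loess -> clipped restricted minimum, independently coded."""
    rpt = np.rint(np.asarray(rpt, float)).astype(int)
    correct = np.asarray(correct, float)
    centers, counts, hits = [], [], []
    for v in np.unique(rpt):
        m = rpt == v
        centers.append(v)
        counts.append(m.sum())
        hits.append(correct[m].sum())
    centers = np.asarray(centers, float)
    p_hat = np.asarray(hits) / np.asarray(counts)
    grid = np.arange(grid_lo, grid_hi + 1)
    fit = np.clip(loess_wls(centers, p_hat, grid, span, degree), 0.0, 1.0)
    return float(fit[grid > restriction].min())


def exhaustive_min_diff_p(rpt, correct, n_a, span=0.2, degree=2,
                          restriction=0.0, tol=1e-12):
    """Exact two-sided permutation p for the difference of restricted minima,
    enumerating every distinct relabelling (identity included)."""
    rpt = np.asarray(rpt, float)
    correct = np.asarray(correct, float)
    n = len(rpt)
    obs = restricted_min_wls(rpt[:n_a], correct[:n_a], span, degree, restriction) \
        - restricted_min_wls(rpt[n_a:], correct[n_a:], span, degree, restriction)
    stats = []
    for pick in combinations(range(n), n_a):
        sel = np.zeros(n, bool)
        sel[list(pick)] = True
        stat = restricted_min_wls(rpt[sel], correct[sel], span, degree, restriction) \
            - restricted_min_wls(rpt[~sel], correct[~sel], span, degree, restriction)
        stats.append(stat)
    stats = np.asarray(stats)
    return float(np.mean(np.abs(stats) >= abs(obs) - tol)), obs, stats


def log10_bf_trapezoid(k, n, side, prior_scale=0.5, n_points=1_000_001,
                       upper=30.0):
    """Dense trapezoid quadrature for the one-sided proportion Bayes factor
    (point null p = 0.5 vs truncated logistic prior on the log-odds)."""
    sgn = 1.0 if side == "above" else -1.0
    t = np.linspace(1e-12, upper, n_points)
    om = sgn * t
    p = expit(om)
    with np.errstate(divide="ignore"):
        loglik = k * np.log(2.0 * p) + (n - k) * np.log(2.0 * (1.0 - p))
    logprior = np.log(2.0) + logistic.logpdf(om, loc=0.0, scale=prior_scale)
    g = loglik + logprior
    m = g.max()
    integral = np.trapezoid(np.exp(g - m), t)
    return (m + np.log(integral)) / np.log(10.0)
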