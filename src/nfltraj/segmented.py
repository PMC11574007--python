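"""Segmented (breakpoint) regression for bifurcation points in NfL trajectories.

Implements the standard iterative-linearization scheme for one breakpoint:
given a current estimate psi, fit y ~ x + (x-psi)_+ + gap-indicator, update
psi by gap/slope-change, and repeat to convergence. The slope-change test
against the linear null is a score-type supremum test with a Davies bound on
the p-value (the breakpoint is a nuisance parameter absent under the null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as st

from .errors import FitError

__all__ = ["BreakpointFit", "fit_segmented", "segmented_multistart",
           "davies_test", "detect_bifurcation"]


@dataclass
class BreakpointFit:
    psi: float
    left_slope: float
    right_slope: float
    psi_se: float
    iterations: int
    converged: bool
    slope_change: float
    slope_change_se: float
    davies_p: float
    rss: float
    linear_rss: float


def _ols(X, y):
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    dof = len(y) - X.shape[1]
    sigma2 = rss / max(dof, 1)
    XtX_inv = np.linalg.pinv(X.T @ X)
    return coef, rss, sigma2 * XtX_inv


def fit_segmented(x, y, psi_init: float, tol: float = 1e-6,
                  max_iter: int = 100) -> BreakpointFit:
    """One-breakpoint segmented regression via iterative linearization."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 10:
        raise FitError(f"segmented regression needs >= 10 points, got {len(x)}")
    lo, hi = float(np.min(x)), float(np.max(x))
    if not lo < psi_init < hi:
        raise FitError(f"psi_init {psi_init} outside the data range ({lo}, {hi})")

    span = hi - lo
    eps = 1e-3 * span
    psi = float(psi_init)
    coef = None
    cov = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U = np.clip(x - psi, 0.0, None)
        V = -(x > psi).astype(float)
        X = np.column_stack([np.ones_like(x), x, U, V])
        coef, _, cov = _ols(X, y)
        beta_u, gamma = coef[2], coef[3]
        if abs(beta_u) < 1e-12:
            break
        step = gamma / beta_u
        psi_new = float(np.clip(psi + step, lo + eps, hi - eps))
        if abs(psi_new - psi) < tol:
            psi = psi_new
            converged = True
            break
        psi = psi_new

    # final refit without the gap term at the converged breakpoint
    U = np.clip(x - psi, 0.0, None)
    Xf = np.column_stack([np.ones_like(x), x, U])
    coef_f, rss, cov_f = _ols(Xf, y)
    _, lin_rss, _ = _ols(np.column_stack([np.ones_like(x), x]), y)

    beta_u = float(coef_f[2])
    se_u = float(np.sqrt(max(cov_f[2, 2], 0.0)))
    se_gamma = float(np.sqrt(max(cov[3, 3], 0.0))) if cov is not None else np.nan
    psi_se = se_gamma / abs(beta_u) if abs(beta_u) > 1e-12 else np.inf
    return BreakpointFit(
        psi=psi,
        left_slope=float(coef_f[1]),
        right_slope=float(coef_f[1] + beta_u),
        psi_se=float(psi_se),
        iterations=it,
        converged=converged,
        slope_change=beta_u,
        slope_change_se=se_u,
        davies_p=davies_test(x, y),
        rss=rss,
        linear_rss=lin_rss,
    )


def segmented_multistart(x, y, start_quantiles=(0.15, 0.25, 0.35, 0.5, 0.65, 0.75, 0.85),
                         **kw) -> BreakpointFit:
    """Best-RSS segmented fit across several breakpoint initializations."""
    x = np.asarray(x, float)
    best = None
    for q in start_quantiles:
        psi0 = float(np.quantile(x, q))
        if not np.min(x) < psi0 < np.max(x):
            continue
        try:
            fit = fit_segmented(x, y, psi0, **kw)
        except FitError:
            continue
        if best is None or fit.rss < best.rss:
            best = fit
    if best is None:
        raise FitError("no valid segmented fit from any start")
    return best


def davies_test(x, y, n_points: int = 10) -> float:
    """Davies-bound p-value for a slope change at an unknown breakpoint.

    Computes the t statistic of the (x-psi)_+ term over a grid of candidate
    breakpoints (interior quantiles) and bounds the two-sided probability
    that the supremum exceeds the observed maximum:
    p <= 2*[Phi(-M) + V*exp(-M^2/2)/sqrt(8*pi)], V = total variation of the
    t path.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    qs = np.linspace(0.1, 0.9, n_points)
    psis = np.unique(np.quantile(x, qs))
    ts = []
    for psi in psis:
        U = np.clip(x - psi, 0.0, None)
        X = np.column_stack([np.ones_like(x), x, U])
        if np.linalg.matrix_rank(X) < 3:
            continue
        coef, _, cov = _ols(X, y)
        se = np.sqrt(max(cov[2, 2], 0.0))
        if se > 0:
            ts.append(coef[2] / se)
    if not ts:
        return 1.0
    ts = np.asarray(ts)
    M = float(np.max(np.abs(ts)))
    V = float(np.sum(np.abs(np.diff(ts))))
    p = 2.0 * (st.norm.sf(M) + V * np.exp(-0.5 * M**2) / np.sqrt(8.0 * np.pi))
    return float(min(p, 1.0))


def detect_bifurcation(eyo, values, alpha: float = 0.05,
                       se_guard_fraction: float = 0.25) -> BreakpointFit | None:
    """Segmented fit with a no-bifurcation decision rule.

    Returns None when the slope-change (Davies) test is non-significant at
    ``alpha``, when the breakpoint is too imprecise (SE above
    ``se_guard_fraction`` of the EYO range), or when the segmented fit does
    not improve on the simple linear fit.
    """
    x = np.asarray(eyo, float)
    y = np.asarray(values, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    fit = segmented_multistart(x, y)
    span = float(np.ptp(x))
    if fit.davies_p > alpha:
        return None
    if not np.isfinite(fit.psi_se) or fit.psi_se > se_guard_fraction * span:
        return None
    if fit.rss > fit.linear_rss:
        return None
    return fit
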