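"""Bayesian restricted-cubic-spline mixed models of NfL against disease time.

The outcome (baseline log10 NfL, or an extracted annualized rate of change)
is modelled as

    y = b0 + b_mc*MC + b_lin*EYO + b_cub*rcs(EYO)
        + b_lin:mc*MC*EYO + b_cub:mc*MC*rcs(EYO)
        + b_age*age + b_sex*sex + b_bmi*BMI + u_family + e,

    u_family ~ N(0, sigma_f^2),  e ~ N(0, sigma_e^2).

Posterior sampling is collapsed-Gibbs-style and exploits the model's
Gaussian structure twice: the family intercepts are marginalized
analytically (each family block has compound-symmetric covariance, handled
in closed form via Sherman–Morrison), and, given the two variance
parameters, the fixed-effect posterior is an exact multivariate normal that
is also integrated in closed form. An MCMC ensemble (emcee, differential-
evolution moves) therefore only has to explore the 2-D marginal posterior of
(log sigma_f, log sigma_e); fixed-effect draws are then sampled exactly from
their conditional normal at each kept variance draw, so they carry no
ensemble autocorrelation. Walkers are treated as chains for split-R-hat /
ESS diagnostics.

The group difference curve MC(e) - NC(e) at fixed covariates depends only on
the mutation-status main effect and its two spline interactions, so the
divergence point — the first EYO on a left-to-right grid scan where the
equal-tailed 95% credible interval of the difference excludes 0 — is read
directly off the posterior draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FitError
from .splines import SplineSpec, choose_knots, rcs_basis

__all__ = [
    "PriorSpec",
    "SamplerSettings",
    "TrajectoryFit",
    "DivergenceResult",
    "fit_trajectory_model",
    "divergence_point",
]

TERMS = ("intercept", "status", "eyo_linear", "eyo_cubic",
         "status_x_linear", "status_x_cubic", "age", "sex", "bmi")


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors on the standardized-design scale."""

    beta_sd: float = 10.0          # Normal(0, beta_sd^2) per fixed effect
    sd_halfnormal_scale: float = 5.0  # half-Normal on sigma_f and sigma_e


@dataclass(frozen=True)
class SamplerSettings:
    walkers: int = 16
    steps: int = 1200
    burn: int = 600
    thin: int = 2
    rhat_limit: float = 1.01


@dataclass
class TrajectoryFit:
    outcome: str
    spec: SplineSpec
    beta: np.ndarray            # (chains, draws, 9) standardized-design scale
    sigma_family: np.ndarray    # (chains, draws)
    sigma_resid: np.ndarray     # (chains, draws)
    col_means: np.ndarray
    col_sds: np.ndarray
    covariate_reference: dict   # age / sex / bmi values for group curves
    eyo_range: tuple[float, float]
    rhat: dict
    ess: dict
    converged: bool
    n_obs: int
    n_families: int

    @property
    def n_draws(self) -> int:
        return int(self.beta.shape[0] * self.beta.shape[1])

    def beta_flat(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])

    def coefficient_table(self) -> pd.DataFrame:
        """Posterior summary on the original (unstandardized) predictor scale."""
        draws = self.beta_flat().copy()
        orig = draws / self.col_sds  # intercept handled below
        orig[:, 0] = draws[:, 0] - (draws[:, 1:] * self.col_means[1:] / self.col_sds[1:]).sum(axis=1)
        rows = []
        for j, name in enumerate(TERMS):
            q = np.percentile(orig[:, j], [2.5, 50, 97.5])
            rows.append(dict(term=name, median=q[1], lo95=q[0], hi95=q[2],
                             rhat=self.rhat[name], ess=self.ess[name]))
        return pd.DataFrame(rows)


@dataclass
class DivergenceResult:
    first_divergence_eyo: float | None
    difference_curve: pd.DataFrame  # columns: eyo, median, lo, hi
    persistence_flag: bool
    # first grid EYO from which the credible band excludes 0 at *every*
    # later grid point; robust to isolated noise crossings at the sparse
    # edges of the EYO range (equals first_divergence_eyo when the literal
    # first crossing already persists)
    first_persistent_divergence_eyo: float | None = None


def _design(df: pd.DataFrame, outcome: str, spec: SplineSpec):
    eyo = df["eyo"].to_numpy(float)
    status = df["status"].to_numpy(float)
    lin, cub = rcs_basis(eyo, spec)
    X = np.column_stack([
        np.ones_like(eyo), status, lin, cub, status * lin, status * cub,
        df["age"].to_numpy(float), df["sex"].to_numpy(float), df["bmi"].to_numpy(float),
    ])
    y = df[outcome].to_numpy(float)
    return X, y


def _standardize(X):
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    means[0], sds[0] = 0.0, 1.0  # intercept untouched
    sds[sds < 1e-12] = 1.0
    return (X - means) / sds, means, sds


def fit_trajectory_model(
    data: pd.DataFrame,
    outcome: str,
    spec: SplineSpec | None = None,
    priors: PriorSpec | None = None,
    sampler: SamplerSettings | None = None,
    seed: int = 0,
) -> TrajectoryFit:
    """Sample the posterior of the spline LMM for one outcome.

    ``data`` needs columns outcome, eyo, status (1=carrier), age, sex
    (1=male), bmi, family_id; incomplete cases are dropped.
    """
    import emcee

    priors = priors or PriorSpec()
    sampler_cfg = sampler or SamplerSettings()

    cols = [outcome, "eyo", "status", "age", "sex", "bmi", "family_id"]
    df = data[cols].dropna().reset_index(drop=True)
    if len(df) < 20:
        raise FitError(f"too few complete cases ({len(df)}) for outcome {outcome!r}")
    if spec is None:
        spec = choose_knots(df["eyo"])

    X, y = _design(df, outcome, spec)
    Xs, means, sds = _standardize(X)
    cond = np.linalg.cond(Xs)
    if cond > 1e6:
        warnings.warn(f"ill-conditioned design (condition number {cond:.2e})")

    # family blocks: sort rows by family for contiguous segments
    fam_codes = pd.factorize(df["family_id"])[0]
    order = np.argsort(fam_codes, kind="stable")
    Xs, y, fam_codes = Xs[order], y[order], fam_codes[order]
    starts = np.concatenate([[0], 1 + np.nonzero(np.diff(fam_codes))[0]])
    fam_sizes = np.diff(np.concatenate([starts, [len(y)]])).astype(int)
    n_fam = len(starts)
    n, p = Xs.shape

    beta_sd2 = priors.beta_sd**2
    hn_scale2 = priors.sd_halfnormal_scale**2

    # Sufficient statistics for the collapsed evidence. Family-block inverses
    # follow Sherman-Morrison; the family sums enter only through outer
    # products grouped by family size, so everything is precomputable.
    G = Xs.T @ Xs
    h = Xs.T @ y
    yy = float(y @ y)
    xfam = np.add.reduceat(Xs, starts, axis=0)          # (F, p)
    yfam = np.add.reduceat(y, starts)                   # (F,)
    uniq_sizes, size_inv = np.unique(fam_sizes, return_inverse=True)
    n_sizes = len(uniq_sizes)
    M = np.zeros((n_sizes, p, p))
    v = np.zeros((n_sizes, p))
    q = np.zeros(n_sizes)
    counts = np.zeros(n_sizes)
    for f in range(n_fam):
        s = size_inv[f]
        M[s] += np.outer(xfam[f], xfam[f])
        v[s] += xfam[f] * yfam[f]
        q[s] += yfam[f] ** 2
        counts[s] += 1
    prior_prec = np.eye(p) / beta_sd2
    _, logdet_prior_cov = np.linalg.slogdet(np.eye(p) * beta_sd2)

    def _posterior_pieces(sf2, se2):
        """Conditional-normal pieces for beta given the two variances."""
        w = sf2 / (se2 * (se2 + uniq_sizes * sf2))      # per distinct size
        P = G / se2 - np.tensordot(w, M, axes=1) + prior_prec
        b = h / se2 - w @ v
        yquad = yy / se2 - float(w @ q)
        logdet_V = float(
            np.sum(counts * ((uniq_sizes - 1) * np.log(se2) + np.log(se2 + uniq_sizes * sf2)))
        )
        return P, b, yquad, logdet_V

    def log_prob(theta):
        theta = np.atleast_2d(theta)
        out = np.empty(len(theta))
        for i, (log_sf, log_se) in enumerate(theta):
            if not (-15 < log_sf < 15 and -15 < log_se < 15):
                out[i] = -np.inf
                continue
            sf2, se2 = np.exp(2 * log_sf), np.exp(2 * log_se)
            P, b, yquad, logdet_V = _posterior_pieces(sf2, se2)
            try:
                L = np.linalg.cholesky(P)
            except np.linalg.LinAlgError:
                out[i] = -np.inf
                continue
            m = np.linalg.solve(P, b)
            logdet_P = 2.0 * float(np.sum(np.log(np.diag(L))))
            ll = -0.5 * (logdet_V + logdet_prior_cov + logdet_P + yquad - float(b @ m))
            lp = -0.5 * (sf2 + se2) / hn_scale2 + log_sf + log_se
            val = ll + lp
            out[i] = val if np.isfinite(val) else -np.inf
        return out

    rng = np.random.RandomState(seed)
    beta0, *_ = np.linalg.lstsq(Xs, y, rcond=None)
    s0 = max(float(np.std(y - Xs @ beta0)), 1e-4)
    center = np.array([np.log(s0 / 2.0), np.log(s0)])
    p0 = center[None, :] + 0.1 * rng.standard_normal((sampler_cfg.walkers, 2))

    es = emcee.EnsembleSampler(
        sampler_cfg.walkers, 2, log_prob, vectorize=True,
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    es.random_state = rng.get_state()
    es.run_mcmc(p0, sampler_cfg.steps, progress=False, skip_initial_state_check=True)
    chain = es.get_chain()  # (steps, walkers, 2)
    kept = np.moveaxis(chain[sampler_cfg.burn :: sampler_cfg.thin], 0, 1)
    n_chains, n_kept, _ = kept.shape

    # exact conditional normal draw of beta at every kept variance draw
    draws = np.empty((n_chains, n_kept, p + 2))
    draws[:, :, p] = kept[:, :, 0]
    draws[:, :, p + 1] = kept[:, :, 1]
    for c in range(n_chains):
        for d in range(n_kept):
            sf2, se2 = np.exp(2 * kept[c, d, 0]), np.exp(2 * kept[c, d, 1])
            P, b, _, _ = _posterior_pieces(sf2, se2)
            L = np.linalg.cholesky(P)
            m = np.linalg.solve(P, b)
            z = rng.standard_normal(p)
            draws[c, d, :p] = m + np.linalg.solve(L.T, z)

    rhat, ess = _diagnostics(draws)
    converged = all(np.isfinite(v) and v < sampler_cfg.rhat_limit for v in rhat.values())

    ref = dict(
        age=float(df["age"].mean()),
        sex=float(df["sex"].mean()),
        bmi=float(df["bmi"].mean()),
    )
    if draws.shape[0] * draws.shape[1] < 4000:
        warnings.warn(
            f"only {draws.shape[0] * draws.shape[1]} post-warmup draws kept; "
            "the sampler contract asks for >= 4000")
    return TrajectoryFit(
        outcome=outcome,
        spec=spec,
        beta=draws[:, :, :p],
        sigma_family=np.exp(draws[:, :, p]),
        sigma_resid=np.exp(draws[:, :, p + 1]),
        col_means=means,
        col_sds=sds,
        covariate_reference=ref,
        eyo_range=(float(df["eyo"].min()), float(df["eyo"].max())),
        rhat=rhat,
        ess=ess,
        converged=bool(converged),
        n_obs=len(df),
        n_families=n_fam,
    )


def _diagnostics(draws):
    """Split-R-hat and bulk ESS per parameter, walkers as chains."""
    import arviz as az

    names = list(TERMS) + ["log_sigma_family", "log_sigma_resid"]
    rhat, ess = {}, {}
    for j, name in enumerate(names):
        arr = draws[:, :, j]
        data = az.convert_to_dataset(arr[:, :, None].squeeze(-1))
        rhat[name] = float(az.rhat(data)["x"].values)
        ess[name] = float(az.ess(data)["x"].values)
    return rhat, ess


def default_grid(fit: TrajectoryFit, lo: float = -30.0, hi: float = 15.0,
                 step: float = 0.1) -> np.ndarray:
    """EYO grid for divergence scans, truncated to the observed EYO range."""
    lo = max(lo, fit.eyo_range[0])
    hi = min(hi, fit.eyo_range[1])
    return np.round(np.arange(lo, hi + step / 2, step), 6)


def divergence_point(fit: TrajectoryFit, grid: np.ndarray | None = None,
                     force: bool = False) -> DivergenceResult:
    """First EYO where the 95% credible interval of MC-NC excludes 0.

    Group curves are evaluated at reference covariates (sample means; sex at
    its sample proportion), which cancel in the difference: only the status
    main effect and the two spline-by-status interactions contribute.
    """
    if not fit.converged and not force:
        raise FitError("refusing divergence scan on a non-converged fit (use force=True)")
    if grid is None:
        grid = default_grid(fit)
    lin, cub = rcs_basis(grid, fit.spec)
    ref = fit.covariate_reference

    def row(status, e_lin, e_cub):
        return np.array([
            1.0, status, e_lin, e_cub, status * e_lin, status * e_cub,
            ref["age"], ref["sex"], ref["bmi"],
        ])

    beta = fit.beta_flat()  # standardized scale
    diff_design = np.stack([
        (row(1.0, l, c) - row(0.0, l, c)) / fit.col_sds for l, c in zip(lin, cub)
    ])  # means cancel in the difference of two standardized rows
    delta = diff_design @ beta.T  # (grid, draws)
    lo_q, med, hi_q = np.percentile(delta, [2.5, 50.0, 97.5], axis=1)
    excl = (lo_q > 0) | (hi_q < 0)
    curve = pd.DataFrame(dict(eyo=grid, median=med, lo=lo_q, hi=hi_q))
    if not excl.any():
        return DivergenceResult(None, curve, False)
    first = int(np.argmax(excl))
    persists = bool(excl[first:].all())
    # earliest point from which exclusion holds all the way to the end,
    # requiring a consistent sign of the difference
    persistent = None
    sign_pos = med[-1] > 0
    run_ok = excl & ((lo_q > 0) if sign_pos else (hi_q < 0))
    suffix = np.logical_and.accumulate(run_ok[::-1])[::-1]
    if suffix.any() and run_ok[-1]:
        persistent = float(grid[int(np.argmax(suffix))])
    return DivergenceResult(float(grid[first]), curve, persists, persistent)
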