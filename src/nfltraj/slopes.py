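"""Within-person rates of change and CSF-vs-plasma association analyses.

The annualized rate of change of a log10 analyte for each participant is the
fixed time effect plus the participant's empirical-Bayes (BLUP) random slope
from an LMM with a family random intercept and per-participant random
intercept and slope. Cross-sectional and longitudinal CSF-plasma relations
use Pearson correlation and covariate-adjusted linear regression, candidate
covariate sets are ranked by AIC / Akaike weights, clinical groups are
compared with family-clustered LMMs and Holm-adjusted pairwise contrasts,
and the plasma/CSF ratio is analyzed on the absolute pg/ml scale.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from ._lmm import fit_family_subject_lmm, subject_slope_blups
from .errors import FitError, NflTrajError

__all__ = [
    "extract_subject_slopes",
    "relate_csf_plasma",
    "aic_select",
    "compare_groups",
    "plasma_csf_ratio",
]


def extract_subject_slopes(visits: pd.DataFrame, analyte: str,
                           participants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-subject annualized slope of ``log10_<analyte>`` (or any column).

    Returns columns participant_id, analyte, annualized_slope, n_visits_used.
    Subjects contribute with any number of visits; single-visit subjects are
    shrunk to the population mean slope. When every subject's data are
    exactly linear (zero residual variance) the mixed model's MLE sits on the
    variance boundary and the BLUPs converge to the per-subject OLS slopes;
    that exact limit is returned directly.
    """
    # rates of change are extracted on the log10 scale when available
    col = f"log10_{analyte}" if f"log10_{analyte}" in visits.columns else analyte
    if col not in visits.columns:
        raise NflTrajError(f"analyte column {analyte!r} not found in visit table")
    df = visits[["participant_id", "visit_index", "time_from_baseline", col]].dropna()
    if participants is not None:
        fam = participants.set_index("participant_id")["family_id"]
        df = df.assign(family_id=df["participant_id"].map(fam))
    elif "family_id" in visits.columns:
        df = df.assign(family_id=visits.loc[df.index, "family_id"])
    else:
        df = df.assign(family_id="F0")
    df = df.rename(columns={col: "y", "time_from_baseline": "time"})
    counts = df.groupby("participant_id").size()

    exact = _exact_linear_slopes(df)
    if exact is not None:
        slopes = exact
    else:
        res = fit_family_subject_lmm(df, "y ~ time", random_slope=True)
        blups = subject_slope_blups(res, df)
        slopes = res.fe_params["time"] + blups

    out = pd.DataFrame(dict(
        participant_id=slopes.index,
        analyte=analyte,
        annualized_slope=slopes.to_numpy(float),
        n_visits_used=counts.reindex(slopes.index).fillna(0).astype(int).to_numpy(),
    ))
    return out.sort_values("participant_id").reset_index(drop=True)


def _exact_linear_slopes(df: pd.DataFrame):
    """Detect the zero-residual degenerate case; return exact OLS slopes if so."""
    slopes = {}
    max_resid = 0.0
    for pid, g in df.groupby("participant_id"):
        t, y = g["time"].to_numpy(float), g["y"].to_numpy(float)
        if len(t) < 2 or np.ptp(t) == 0:
            return None  # cannot certify exact linearity for everyone
        b, a = np.polyfit(t, y, 1)
        max_resid = max(max_resid, float(np.max(np.abs(y - (a + b * t)))))
        slopes[pid] = float(b)
    scale = max(1.0, float(df["y"].abs().max()))
    if max_resid > 1e-10 * scale:
        return None
    return pd.Series(slopes)


def relate_csf_plasma(pairs: pd.DataFrame, covariates=("age", "sex", "bmi")) -> dict:
    """Pearson and covariate-adjusted association of CSF on plasma log10 NfL.

    ``pairs`` columns: csf, plasma, plus covariates. Returns unadjusted r2/p,
    adjusted full-model r2, partial r2 for the plasma term, and the OLS
    coefficient table.
    """
    df = pairs.dropna(subset=["csf", "plasma"]).copy()
    if len(df) < 3:
        raise NflTrajError(f"need >= 3 complete pairs, got {len(df)}")
    r, p = st.pearsonr(df["plasma"], df["csf"])
    covs = [c for c in covariates if c in df.columns]
    rhs = " + ".join(["plasma"] + covs)
    full = smf.ols(f"csf ~ {rhs}", data=df).fit()
    result = dict(n=int(len(df)), r=float(r), r2=float(r**2), p=float(p),
                  adjusted_r2=float(full.rsquared),
                  coefficients=full.params.to_dict(),
                  coefficient_se=full.bse.to_dict())
    if covs:
        reduced = smf.ols("csf ~ " + " + ".join(covs), data=df).fit()
        sse_f, sse_r = full.ssr, reduced.ssr
        result["partial_r2_plasma"] = float((sse_r - sse_f) / sse_r) if sse_r > 0 else np.nan
    return result


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights w_i = exp(-d_i/2)/sum_j exp(-d_j/2); shift-invariant."""
    a = np.asarray(aics, dtype=float)
    d = a - a.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def aic_select(data: pd.DataFrame, outcome: str, base_terms=("plasma",),
               candidate_covariates=("age", "sex", "bmi")) -> pd.DataFrame:
    """AIC table over all subsets of the candidate covariates.

    Akaike weights w_i = exp(-d_i/2)/sum_j exp(-d_j/2); rows sorted by AIC
    ascending with the cumulative weight alongside. All candidates are fit on
    the common complete-case rows so AICs are comparable.
    """
    need = [outcome, *base_terms, *candidate_covariates]
    df = data[[c for c in need if c in data.columns]].dropna()
    sets = [tuple(s) for r in range(len(candidate_covariates) + 1)
            for s in itertools.combinations(candidate_covariates, r)]
    if len(sets) < 2:
        raise NflTrajError("need at least 2 candidate models")
    rows = []
    for s in sets:
        rhs = " + ".join(list(base_terms) + list(s)) or "1"
        res = smf.ols(f"{outcome} ~ {rhs}", data=df).fit()
        rows.append(dict(covariates="+".join(s) if s else "(none)", aic=float(res.aic)))
    tab = pd.DataFrame(rows)
    tab["delta_aic"] = tab["aic"] - tab["aic"].min()
    tab["weight"] = akaike_weights(tab["aic"])
    tab = tab.sort_values("aic", kind="stable").reset_index(drop=True)
    tab["cumulative_weight"] = tab["weight"].cumsum()
    return tab


def compare_groups(slopes: pd.DataFrame, stages: pd.DataFrame,
                   participants: pd.DataFrame, value_col: str = "annualized_slope",
                   correction: str = "holm", min_group: int = 2) -> pd.DataFrame:
    """All pairwise clinical-group contrasts of per-subject values.

    One LMM per analyte: value ~ group + baseline age + sex + baseline BMI
    with a family random intercept; Wald contrasts between group levels with
    residual-df t p-values, then Holm (configurable) adjustment across the
    contrast family. Groups with fewer than ``min_group`` members are omitted
    with a warning.
    """
    pidx = participants.set_index("participant_id")
    df = slopes.merge(stages, on="participant_id")
    df = df[df["stage"] != "reverter_excluded"].copy()
    df["family_id"] = df["participant_id"].map(pidx["family_id"])
    df["age"] = df["participant_id"].map(pidx["baseline_age"])
    df["bmi"] = df["participant_id"].map(pidx["baseline_bmi"])
    df["sex"] = (df["participant_id"].map(pidx["sex"]) == "male").astype(float)
    df = df.rename(columns={value_col: "y"}).dropna(subset=["y", "age", "bmi", "sex"])

    sizes = df["stage"].value_counts()
    groups = [g for g in ("NC", "presymptomatic_MC", "converter_MC", "symptomatic_MC")
              if sizes.get(g, 0) >= min_group]
    for g, n in sizes.items():
        if n < min_group:
            warnings.warn(f"group {g!r} has {n} member(s); its contrasts are omitted")
    df = df[df["stage"].isin(groups)]
    if len(groups) < 2:
        raise FitError("fewer than two clinical groups available for comparison")

    import warnings as _w
    from statsmodels.tools.sm_exceptions import ConvergenceWarning
    formula = ("y ~ C(stage, Treatment('NC')) + age + sex + bmi"
               if "NC" in groups else "y ~ C(stage) + age + sex + bmi")
    with _w.catch_warnings():
        _w.simplefilter("ignore", ConvergenceWarning)
        _w.simplefilter("ignore", RuntimeWarning)
        _w.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, data=df, groups="family_id")
        res = None
        for method in ("lbfgs", "powell", "cg"):
            try:
                res = model.fit(reml=True, method=method, maxiter=500)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if res is None:
            raise FitError("family-clustered group-comparison model failed to fit")

    # map each group to its fixed-effect coordinate vector
    names = list(res.fe_params.index)
    level_vec = {}
    base = np.zeros(len(names))
    base[names.index("Intercept")] = 1.0
    for g in groups:
        v = base.copy()
        for j, nm in enumerate(names):
            if nm.startswith("C(stage") and f"[T.{g}]" in nm:
                v[j] = 1.0
        level_vec[g] = v

    dof = max(int(len(df) - len(names) - 1), 1)
    cov = res.cov_params().iloc[: len(names), : len(names)].to_numpy()
    fe = res.fe_params.to_numpy()
    rows = []
    for a, b in itertools.combinations(groups, 2):
        L = level_vec[b] - level_vec[a]
        est = float(L @ fe)
        se = float(np.sqrt(L @ cov @ L))
        t = est / se if se > 0 else np.nan
        praw = float(2 * st.t.sf(abs(t), dof)) if np.isfinite(t) else np.nan
        rows.append(dict(contrast=f"{b} - {a}", estimate=est, se=se,
                         t=t, df=dof, p_raw=praw))
    out = pd.DataFrame(rows)
    adj = multipletests(out["p_raw"].fillna(1.0), method=correction)[1]
    out["p_adjusted"] = np.maximum(adj, out["p_raw"])
    out["correction"] = correction
    return out


def plasma_csf_ratio(visits: pd.DataFrame) -> pd.DataFrame:
    """Per-visit plasma/CSF NfL ratio on the absolute pg/ml scale."""
    df = visits.dropna(subset=["plasma_nfl", "csf_nfl"]).copy()
    if (df["csf_nfl"] <= 0).any():
        raise NflTrajError("csf_nfl must be positive to form the plasma/CSF ratio")
    df["plasma_csf_ratio"] = df["plasma_nfl"] / df["csf_nfl"]
    return df[["participant_id", "visit_index", "plasma_csf_ratio"]].reset_index(drop=True)


def baseline_ratio_table(visits: pd.DataFrame) -> pd.DataFrame:
    """First-visit ratio per participant, shaped for compare_groups."""
    ratios = plasma_csf_ratio(visits)
    first = ratios.sort_values(["participant_id", "visit_index"]).groupby(
        "participant_id", as_index=False).first()
    return first.rename(columns={"plasma_csf_ratio": "annualized_slope"})[
        ["participant_id", "annualized_slope"]].assign(analyte="plasma_csf_ratio")
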