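"""Coupling between NfL rate of change and imaging rates of change.

Tests whether the per-person annualized NfL slope predicts the slope of a
time-varying imaging outcome (ICV-adjusted precuneus grey-matter volume, or
PiB-PET SUVR). The mixed model per clinical group is

    imaging ~ time * (baseline age + sex + baseline BMI + NfL slope)

with random intercept for family and random intercept + slope per
participant; the term of interest is the NfL-slope-by-time interaction
(imaging units per year per unit NfL slope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from ._lmm import fit_family_subject_lmm
from .errors import FitError, NflTrajError

__all__ = ["CouplingResult", "adjust_volume_for_icv", "fit_imaging_coupling"]


@dataclass
class CouplingResult:
    group: str
    analyte: str
    imaging_outcome: str
    interaction_estimate: float
    se: float
    p: float
    n: int
    random_slope_used: bool


def adjust_volume_for_icv(volume, icv, reference_mask) -> np.ndarray:
    """Residual-method adjustment of regional volume for intracranial volume.

    The volume~ICV slope is estimated in the reference group (non-carriers)
    and the fitted ICV contribution, centered at the reference-group mean
    ICV, is removed from everyone, so adjusted volume is uncorrelated with
    ICV within the reference group.
    """
    v = np.asarray(volume, float)
    i = np.asarray(icv, float)
    ref = np.asarray(reference_mask, bool)
    if (v[np.isfinite(v)] <= 0).any() or (i[np.isfinite(i)] <= 0).any():
        raise NflTrajError("volumes and ICV must be positive")
    ok = ref & np.isfinite(v) & np.isfinite(i)
    if ok.sum() < 10:
        raise NflTrajError(f"reference group too small for ICV adjustment ({ok.sum()} < 10)")
    i_ref_mean = i[ok].mean()
    if np.ptp(i[ok]) == 0:
        return v.copy()
    slope = float(np.polyfit(i[ok], v[ok], 1)[0])
    return v - slope * (i - i_ref_mean)


def fit_imaging_coupling(imaging_visits: pd.DataFrame, slope_table: pd.DataFrame,
                         participants: pd.DataFrame, outcome: str,
                         group_label: str = "", min_group: int = 10) -> CouplingResult:
    """Interaction between the NfL rate of change and time for one group.

    ``imaging_visits`` columns: participant_id, time_from_baseline, outcome.
    ``slope_table`` is the output of extract_subject_slopes for one analyte.
    Falls back to a random-intercept-only participant structure (with a
    warning) when the group is too small for random slopes.
    """
    pidx = participants.set_index("participant_id")
    analyte = str(slope_table["analyte"].iloc[0]) if len(slope_table) else "?"
    df = imaging_visits[["participant_id", "time_from_baseline", outcome]].dropna()
    df = df.merge(slope_table[["participant_id", "annualized_slope"]], on="participant_id")
    df = df.rename(columns={"time_from_baseline": "time", outcome: "y",
                            "annualized_slope": "nfl_slope"})
    df["family_id"] = df["participant_id"].map(pidx["family_id"])
    df["age"] = df["participant_id"].map(pidx["baseline_age"])
    df["bmi"] = df["participant_id"].map(pidx["baseline_bmi"])
    df["sex"] = (df["participant_id"].map(pidx["sex"]) == "male").astype(float)
    df = df.dropna()
    n_subj = df["participant_id"].nunique()
    if n_subj < 3:
        raise FitError(f"too few participants ({n_subj}) with imaging for group {group_label!r}")

    formula = "y ~ time * (age + sex + bmi + nfl_slope)"
    exact = _exact_deterministic(df)
    if exact is not None:
        est, se, p, used_slope = exact, 0.0, 0.0, True
    else:
        used_slope = n_subj >= min_group
        if not used_slope:
            warnings.warn(
                f"group {group_label!r} too small for random slopes; "
                "falling back to random intercepts only")
        res = fit_family_subject_lmm(df, formula, random_slope=used_slope)
        est = float(res.fe_params["time:nfl_slope"])
        se = float(res.bse_fe["time:nfl_slope"])
        dof = max(len(df) - len(res.fe_params) - 1, 1)
        p = float(2 * st.t.sf(abs(est / se), dof)) if se > 0 else 0.0
    return CouplingResult(
        group=group_label, analyte=analyte, imaging_outcome=outcome,
        interaction_estimate=est, se=se, p=p, n=int(n_subj),
        random_slope_used=used_slope,
    )


def _exact_deterministic(df: pd.DataFrame):
    """Zero-noise limit: if the full fixed-effect OLS interpolates the data
    exactly, the mixed model's fixed effects equal that OLS solution for any
    covariance weighting; return the exact interaction coefficient."""
    import statsmodels.formula.api as smf

    res = smf.ols("y ~ time * (age + sex + bmi + nfl_slope)", data=df).fit()
    scale = max(1.0, float(df["y"].abs().max()))
    if np.max(np.abs(res.resid)) < 1e-9 * scale:
        return float(res.params["time:nfl_slope"])
    return None
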