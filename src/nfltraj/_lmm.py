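"""Shared linear-mixed-model plumbing on top of statsmodels MixedLM.

All longitudinal models in the pipeline share one random-effects layout:
a random intercept for family, plus random intercept and slope (on time)
for each participant nested within family. statsmodels expresses the
participant terms as variance components inside the family grouping.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import FitError

__all__ = ["fit_family_subject_lmm", "subject_slope_blups"]


def fit_family_subject_lmm(data: pd.DataFrame, formula: str,
                           random_slope: bool = True, reml: bool = True):
    """Fit ``formula`` with family random intercept + per-subject intercept/slope.

    ``data`` must carry family_id, participant_id and time columns. Returns
    the fitted MixedLMResults.
    """
    vc = {"subject": "0 + C(participant_id)"}
    if random_slope:
        vc["subject_time"] = "0 + C(participant_id):time"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)  # boundary variance notices
        model = smf.mixedlm(formula, data=data, groups="family_id",
                            re_formula="1", vc_formula=vc)
        last_exc = None
        for method in ("lbfgs", "powell", "cg"):
            try:
                return model.fit(reml=reml, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
        raise FitError(f"mixed model failed for {formula!r}: {last_exc}") from last_exc


def subject_slope_blups(res, data: pd.DataFrame) -> pd.Series:
    """Per-participant empirical-Bayes slope deviations from a fitted LMM.

    Parses the variance-component BLUP names emitted by MixedLM; returns a
    Series indexed by participant_id (0 for subjects absent from a family's
    BLUP vector, which happens only when their design column is all zero).
    """
    out = {}
    for fam, eff in res.random_effects.items():
        for name, value in eff.items():
            if ":time" not in str(name):
                continue
            pid = _pid_from_vc_name(str(name))
            if pid is not None:
                out[pid] = float(value)
    pids = data["participant_id"].unique()
    return pd.Series({p: out.get(p, 0.0) for p in pids}, name="slope_blup")


def _pid_from_vc_name(name: str):
    # names look like "subject_time[C(participant_id)[P0012]:time]"
    start = name.find("participant_id)[")
    if start == -1:
        return None
    start += len("participant_id)[")
    end = name.find("]", start)
    return name[start:end] if end != -1 else None
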