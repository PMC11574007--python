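"""Descriptive baseline tables and run-report helpers.

The descriptive table mirrors the usual cohort-characteristics layout:
mean (SD) per group for continuous variables with a two-sided Wilcoxon
rank-sum test, n (%) for categorical variables with a two-sided Pearson
chi-square test (no continuity correction). Percentages are always
recomputed from counts; values of 10% or more print to the nearest integer,
below 10% to one decimal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import NflTrajError

__all__ = ["format_percent", "descriptive_table"]


def format_percent(count: int, total: int) -> str:
    """Mixed-precision percentage string: '96%' at >=10%, '3.8%' below."""
    if total <= 0:
        raise NflTrajError("total must be positive")
    p = 100.0 * count / total
    return f"{p:.0f}%" if p >= 10 else f"{p:.1f}%"


CONTINUOUS_DEFAULT = (
    ("baseline_age", "Age (yrs)"),
    ("eyo", "EYO (yrs)"),
    ("baseline_bmi", "BMI"),
    ("mmse", "MMSE"),
    ("precuneus_volume", "Precuneus volume (mm3)"),
    ("precuneus_pib_suvr", "Precuneus PiB-PET (SUVR)"),
    ("plasma_nfl", "Plasma NfL (pg/ml)"),
    ("csf_nfl", "CSF NfL (pg/ml)"),
)


def _baseline_frame(participants: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    base = visits.sort_values(["participant_id", "visit_index"]).groupby(
        "participant_id", as_index=False).first()
    return participants.merge(base, on="participant_id", how="left")


def descriptive_table(participants: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    """Group-wise baseline summary with NC-vs-MC tests.

    Returns long-format rows: variable, level ('' for continuous),
    NC summary, MC summary, p_value.
    """
    df = _baseline_frame(participants, visits)
    groups = {"NC": df[df["mutation_status"] == "noncarrier"],
              "MC": df[df["mutation_status"] == "carrier"]}
    for name, g in groups.items():
        if len(g) == 0:
            raise NflTrajError(f"empty group {name!r} in descriptive table")

    rows = [dict(variable="N", level="",
                 NC=str(len(groups["NC"])), MC=str(len(groups["MC"])), p_value=np.nan)]

    for col, label in CONTINUOUS_DEFAULT:
        if col not in df.columns:
            continue
        a = groups["NC"][col].dropna()
        b = groups["MC"][col].dropna()
        if len(a) == 0 or len(b) == 0:
            continue
        if a.nunique() <= 1 and b.nunique() <= 1 and a.iloc[0] == b.iloc[0]:
            p = 1.0
        else:
            p = float(st.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(dict(
            variable=label, level="",
            NC=f"{a.mean():.1f} ({a.std(ddof=1):.1f})",
            MC=f"{b.mean():.1f} ({b.std(ddof=1):.1f})",
            p_value=p,
        ))

    categorical = [("sex", None)]
    if "cdr_global" in df.columns:
        df = df.assign(cdr_band=pd.cut(
            df["cdr_global"], [-0.1, 0.25, 0.75, 99], labels=["CDR 0", "CDR 0.5", "CDR 1+"]))
        categorical.append(("cdr_band", "CDR global"))
    if "gene" in df.columns and "family_id" in df.columns:
        # non-carriers carry gene='none'; the table reports the family's mutation
        fam_gene = (df[df["gene"] != "none"].groupby("family_id")["gene"]
                    .agg(lambda s: s.iloc[0]))
        df = df.assign(family_gene=df["family_id"].map(fam_gene))
        categorical.append(("family_gene", "Family mutation"))

    for col, label in categorical:
        label = label or col.capitalize()
        sub = df.dropna(subset=[col])
        tab = pd.crosstab(sub[col], sub["mutation_status"])
        for g in ("noncarrier", "carrier"):
            if g not in tab.columns:
                tab[g] = 0
        counts = tab[["noncarrier", "carrier"]].to_numpy()
        nz = counts[counts.sum(axis=1) > 0]
        if nz.shape[0] < 2 or (nz.sum(axis=0) == 0).any():
            p = np.nan
        elif np.allclose(nz[:, 0] / nz[:, 0].sum(), nz[:, 1] / nz[:, 1].sum()):
            p = 1.0
        else:
            p = float(st.chi2_contingency(nz, correction=False)[1])
        totals = counts.sum(axis=0)
        for level, row in zip(tab.index, counts):
            rows.append(dict(
                variable=label, level=str(level),
                NC=f"{row[0]} ({format_percent(int(row[0]), int(totals[0]))})",
                MC=f"{row[1]} ({format_percent(int(row[1]), int(totals[1]))})",
                p_value=p,
            ))
    return pd.DataFrame(rows)
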