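"""Replicate-level assay QC for duplicate Simoa NfL measurements.

Samples are measured in duplicate; the duplicate coefficient of variation
(CV, percent) uses the n-1 sample SD of the pair. Pairs with CV > 20% or a
missing second replicate are flagged. CSF pairs with such flags use the
remeasured pair when one exists; plasma pairs keep the initial values (no
fluid was left for remeasurement) but carry their flags. Absolute NfL values
are log10-transformed before all downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import QCError

__all__ = ["QCPolicy", "replicate_cv", "qc_pipeline", "log10_transform",
           "finalize_visits", "qc_summary"]

FLAG_CV = "cv_gt_20"
FLAG_SINGLE = "single_replicate"
FLAG_REMEASURED = "remeasured_used"
FLAG_INITIAL = "initial_used"


@dataclass(frozen=True)
class QCPolicy:
    cv_threshold_percent: float = 20.0
    remeasure_analytes: tuple[str, ...] = ("csf_nfl",)  # plasma kept initial values


def replicate_cv(rep1, rep2):
    """Duplicate CV in percent: 100 * sample SD (n-1) / mean = 100*|a-b|/(sqrt(2)*mean)."""
    a = np.asarray(rep1, dtype=float)
    b = np.asarray(rep2, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise QCError("replicates must be strictly positive")
    sd = np.abs(a - b) / np.sqrt(2.0)
    out = 100.0 * sd / ((a + b) / 2.0)
    return float(out) if out.ndim == 0 else out


def qc_pipeline(pairs: pd.DataFrame, policy: QCPolicy | None = None) -> pd.DataFrame:
    """Apply duplicate-CV QC to a long replicate table.

    ``pairs`` columns: participant_id, visit_index, analyte, rep1, rep2 and
    optionally remeasured_rep1/remeasured_rep2. Returns one QC record per
    input row (rows are never dropped): cv_percent, flags (comma-joined),
    final_value (mean of the replicates actually used).
    """
    policy = policy or QCPolicy()
    records = []
    for _, row in pairs.iterrows():
        r1, r2 = row.get("rep1"), row.get("rep2")
        rm1, rm2 = row.get("remeasured_rep1"), row.get("remeasured_rep2")
        flags = []
        cv = np.nan
        final = np.nan
        if _present(r1) and _present(r2):
            cv = replicate_cv(r1, r2)
            final = (float(r1) + float(r2)) / 2.0
            if cv > policy.cv_threshold_percent:
                flags.append(FLAG_CV)
        elif _present(r1):
            flags.append(FLAG_SINGLE)
            final = float(r1)
        needs_rescue = bool(flags)
        if needs_rescue:
            has_remeasure = _present(rm1)
            if row["analyte"] in policy.remeasure_analytes and has_remeasure:
                if _present(rm2):
                    final = (float(rm1) + float(rm2)) / 2.0
                    cv = replicate_cv(rm1, rm2)
                else:
                    final = float(rm1)
                flags.append(FLAG_REMEASURED)
            elif np.isfinite(final):
                flags.append(FLAG_INITIAL)
        records.append(
            dict(
                participant_id=row["participant_id"],
                visit_index=row["visit_index"],
                analyte=row["analyte"],
                cv_percent=cv,
                flags=",".join(flags),
                final_value=final,
            )
        )
    return pd.DataFrame(records)


def _present(v) -> bool:
    try:
        return v is not None and np.isfinite(float(v))
    except (TypeError, ValueError):
        return False


def log10_transform(values):
    """Elementwise log10 of positive pg/ml values; errors name offending rows."""
    x = np.asarray(values, dtype=float)
    mask = np.isfinite(x)
    if np.any(x[mask] <= 0):
        bad = np.nonzero(mask & (x <= 0))[0]
        raise QCError(f"nonpositive values at rows {bad.tolist()[:10]}")
    out = np.full_like(x, np.nan)
    out[mask] = np.log10(x[mask])
    return float(out) if out.ndim == 0 else out


def visits_to_replicates(visits: pd.DataFrame) -> pd.DataFrame:
    """Reshape a wide visit table into the long replicate-pair table."""
    frames = []
    for analyte, short in (("plasma_nfl", "plasma"), ("csf_nfl", "csf")):
        cols = dict(rep1=f"{short}_nfl_rep1", rep2=f"{short}_nfl_rep2")
        sub = visits[["participant_id", "visit_index"]].copy()
        sub["analyte"] = analyte
        for k, c in cols.items():
            sub[k] = visits[c] if c in visits.columns else np.nan
        for k in ("remeasured_rep1", "remeasured_rep2"):
            c = f"{short}_nfl_{k}"
            sub[k] = visits[c] if c in visits.columns else np.nan
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def finalize_visits(visits: pd.DataFrame, policy: QCPolicy | None = None) -> pd.DataFrame:
    """Attach QC'd final analyte values and their log10 to the visit table."""
    qc = qc_pipeline(visits_to_replicates(visits), policy)
    out = visits.copy()
    for analyte in ("plasma_nfl", "csf_nfl"):
        sub = qc[qc["analyte"] == analyte].set_index(["participant_id", "visit_index"])
        idx = pd.MultiIndex.from_frame(out[["participant_id", "visit_index"]])
        vals = sub["final_value"].reindex(idx).to_numpy()
        out[analyte] = vals
        with np.errstate(invalid="ignore"):
            out[f"log10_{analyte}"] = log10_transform(np.where(vals > 0, vals, np.nan))
    return out


def qc_summary(qc: pd.DataFrame) -> dict:
    """Flag counts per analyte for the run report."""
    out = {}
    for analyte, grp in qc.groupby("analyte"):
        flags = grp["flags"].str.split(",").explode()
        flags = flags[flags.astype(bool)]
        out[analyte] = dict(
            n_rows=int(len(grp)),
            n_measured=int(grp["final_value"].notna().sum()),
            flag_counts={k: int(v) for k, v in flags.value_counts().items()},
        )
    return out
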