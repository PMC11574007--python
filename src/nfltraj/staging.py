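"""EYO computation, cohort exclusion rules, and CDR-based clinical staging.

Expected onset age for a participant is the mean reported onset age across
carriers of the same variant, falling back to the parental onset age when no
variant-level information exists. EYO (estimated years to symptom onset) is
age at visit minus expected onset, computed identically for carriers and
non-carriers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import StagingError

__all__ = [
    "expected_onset_age",
    "compute_eyo",
    "add_eyo",
    "classify_stage",
    "stage_table",
    "apply_exclusions",
    "STAGES",
]

STAGES = ("NC", "presymptomatic_MC", "converter_MC", "symptomatic_MC", "reverter_excluded")


def expected_onset_age(variant_onsets, parental_onset=None) -> float:
    """Mean of variant-level reported onsets; parental onset as fallback."""
    onsets = [float(v) for v in (variant_onsets or []) if v is not None and np.isfinite(v)]
    if onsets:
        return float(np.mean(onsets))
    if parental_onset is not None and np.isfinite(parental_onset):
        return float(parental_onset)
    raise StagingError("no variant onset ages and no parental onset age available")


def compute_eyo(age_at_visit, expected_onset) -> float:
    """EYO = age at visit - expected onset age (negative before onset)."""
    age = np.asarray(age_at_visit, dtype=float)
    onset = np.asarray(expected_onset, dtype=float)
    if not (np.all(np.isfinite(age)) and np.all(np.isfinite(onset))):
        raise StagingError("age_at_visit and expected_onset must be finite")
    out = age - onset
    return float(out) if out.ndim == 0 else out


def _parse_onsets(cell):
    if cell is None or (isinstance(cell, float) and not np.isfinite(cell)):
        return []
    return [float(v) for v in str(cell).split(";") if v.strip()]


def expected_onset_table(participants: pd.DataFrame) -> pd.Series:
    """Expected onset age per participant, indexed by participant_id."""
    out = {}
    for _, row in participants.iterrows():
        onsets = _parse_onsets(row.get("variant_reported_onsets"))
        parental = row.get("parental_onset_age")
        out[row["participant_id"]] = expected_onset_age(onsets, parental)
    return pd.Series(out, name="expected_onset_age")


def add_eyo(participants: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    """Return visits with an ``eyo`` column derived from expected onset ages."""
    onset = expected_onset_table(participants)
    visits = visits.copy()
    mapped = visits["participant_id"].map(onset)
    if mapped.isna().any():
        missing = visits.loc[mapped.isna(), "participant_id"].unique()
        raise StagingError(f"no expected onset age for participants {list(missing)[:5]}")
    visits["eyo"] = visits["age_at_visit"].to_numpy() - mapped.to_numpy()
    return visits


def classify_stage(cdr_sequence, mutation_status: str) -> str:
    """Classify one participant from their ordered longitudinal CDR values.

    Non-carriers are NC regardless of CDR. Carriers: all CDR 0 ->
    presymptomatic; 0 at baseline then >0 at all later visits -> converter;
    >0 at all visits -> symptomatic; any >0 followed by 0 -> reverter
    (excluded from analyses).
    """
    cdr = [float(c) for c in cdr_sequence if c is not None and np.isfinite(c)]
    if not cdr:
        raise StagingError("empty CDR sequence")
    # reversion check applies to carriers and non-carriers alike
    pos_seen = False
    reverter = False
    for c in cdr:
        if pos_seen and c == 0:
            reverter = True
        if c > 0:
            pos_seen = True
    if mutation_status == "noncarrier":
        return "reverter_excluded" if reverter else "NC"
    if reverter:
        return "reverter_excluded"
    if all(c == 0 for c in cdr):
        return "presymptomatic_MC"
    if all(c > 0 for c in cdr):
        return "symptomatic_MC"
    if cdr[0] == 0 and all(c > 0 for c in cdr[1:]) and len(cdr) >= 2:
        return "converter_MC"
    # 0 at baseline, mixed afterwards without reversion cannot occur
    # (monotone CDR with a 0 after a positive is a reversion) — defensive:
    return "reverter_excluded"


def stage_table(participants: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    """StageLabel per participant from longitudinal CDR."""
    order = visits.sort_values(["participant_id", "visit_index"])
    status = participants.set_index("participant_id")["mutation_status"]
    rows = []
    for pid, grp in order.groupby("participant_id", sort=True):
        rows.append(
            dict(
                participant_id=pid,
                stage=classify_stage(grp["cdr_global"].tolist(), status[pid]),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exclusion rules

RULE_NONPATHOGENIC = "NONPATHOGENIC_VARIANT"
RULE_COMPETING = "COMPETING_DISORDER"
RULE_REVERTER = "REVERTER"
RULE_NC_EYO = "NC_EYO_GT15"


def apply_exclusions(participants: pd.DataFrame, visits: pd.DataFrame,
                     nc_eyo_limit: float = 15.0):
    """Apply the cohort exclusion rules; returns filtered tables + a log.

    Rules, in order: non-pathogenic / Dutch-type-like variants (participant
    level), competing neurological disorders (participant level), CDR
    reverters (participant level), and non-carrier visits with EYO strictly
    greater than 15 years (visit level — data, not people, are dropped).
    Idempotent: a second application removes nothing.
    """
    if "eyo" not in visits.columns:
        visits = add_eyo(participants, visits)
    parts = participants.copy()
    vis = visits.copy()
    log = []

    def drop_participants(pids, rule):
        for pid in pids:
            log.append(dict(participant_id=pid, visit_index="ALL", rule_id=rule))
        return (
            parts[~parts["participant_id"].isin(pids)],
            vis[~vis["participant_id"].isin(pids)],
        )

    if "variant_pathogenic" in parts.columns:
        bad = parts.loc[~parts["variant_pathogenic"].astype(bool), "participant_id"]
        parts, vis = drop_participants(list(bad), RULE_NONPATHOGENIC)

    if "competing_disorder_flag" in parts.columns:
        bad = parts.loc[parts["competing_disorder_flag"].astype(bool), "participant_id"]
        parts, vis = drop_participants(list(bad), RULE_COMPETING)

    stages = stage_table(parts, vis)
    reverters = stages.loc[stages["stage"] == "reverter_excluded", "participant_id"]
    parts, vis = drop_participants(list(reverters), RULE_REVERTER)

    status = parts.set_index("participant_id")["mutation_status"]
    is_nc = vis["participant_id"].map(status).eq("noncarrier")
    over = is_nc & (vis["eyo"] > nc_eyo_limit)
    for _, row in vis.loc[over].iterrows():
        log.append(
            dict(
                participant_id=row["participant_id"],
                visit_index=int(row["visit_index"]),
                rule_id=RULE_NC_EYO,
            )
        )
    vis = vis.loc[~over]
    # participants whose every visit was dropped leave the table as well
    parts = parts[parts["participant_id"].isin(set(vis["participant_id"]))]

    log_df = pd.DataFrame(log, columns=["participant_id", "visit_index", "rule_id"])
    return parts.reset_index(drop=True), vis.reset_index(drop=True), log_df
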