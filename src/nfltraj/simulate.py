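"""Truth-parameterized synthetic ADAD-like cohort generator.

Emulates the longitudinal structure the downstream analyses assume: families
carrying highly penetrant APP/PSEN1/PSEN2 variants, mutation carriers (MC) and
non-carrier family controls (NC), visits every two years (annually once
symptomatic), EYO-anchored log10-NfL trajectories in plasma and CSF with a
carrier-specific acceleration after a true divergence EYO and a plasma-only
rate plateau after a true plateau EYO, CDR conversion spread around EYO 0,
duplicate assay replicates with multiplicative noise, family/subject random
effects, and precuneus MRI-volume / PiB-PET SUVR trajectories whose atrophy
rate is coupled to the true NfL slope in symptomatic carriers only.

The generating mean for a carrier in fluid ``f`` is::

    log10 NfL(t) = base_f + age_f*(age-40) + sex_f*male + bmi_f*(bmi-27.5)
                   + D_f(eyo) + u_family + u_subject + b_subject * t

where the disease rate dD_f/de is a piecewise-linear ramp: 0 before the
divergence EYO ``d``, ``k_f * (e - d)`` after it, and (plasma only) constant
after the plateau EYO ``p``. ``D_f`` is the exact integral of that ramp
(piecewise quadratic), so divergence and plateau truths and per-subject true
annualized slopes are closed-form.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError

__all__ = [
    "FLUIDS",
    "SimConfig",
    "SimTruth",
    "generate_cohort",
    "truth_slopes",
    "disease_level",
    "disease_rate",
    "write_cohort",
    "read_truth",
]

FLUIDS = ("plasma_nfl", "csf_nfl")

# Covariate reference points used by the generating mean (years, kg/m^2).
_AGE_REF = 40.0
_BMI_REF = 27.5


def _default_slope_params():
    # log10 pg/ml per year^2 ramp slope of the disease rate; CSF and plasma
    # trajectories are near-identical presymptomatically, so the ramps match.
    return {"plasma_nfl": 0.0025, "csf_nfl": 0.0025}


def _default_base_levels():
    # log10 of typical non-carrier levels: plasma ~5.8 pg/ml, CSF ~244 pg/ml.
    return {"plasma_nfl": 0.763, "csf_nfl": 2.387}


def _default_covariate_effects():
    # per-fluid (age, male sex, BMI) coefficients on the log10 scale:
    # higher age -> higher NfL in both fluids; lower BMI -> higher plasma NfL;
    # male sex -> higher CSF NfL.
    return {
        "plasma_nfl": {"age": 0.008, "sex_male": 0.0, "bmi": -0.006},
        "csf_nfl": {"age": 0.009, "sex_male": 0.05, "bmi": 0.0},
    }


@dataclass
class SimConfig:
    """Generating parameters of a synthetic cohort; all noise SDs >= 0."""

    n_carriers: int = 355
    n_noncarriers: int = 212
    n_families: int = 140
    visit_interval_years: float = 2.0  # annual once symptomatic
    symptomatic_interval_years: float = 1.0
    n_visits_range: tuple[int, int] = (2, 5)
    eyo_baseline_range: tuple[float, float] = (-30.0, 10.0)
    true_divergence_eyo: float = -20.0
    true_plateau_eyo: float = 3.6
    carrier_slope_params: dict = field(default_factory=_default_slope_params)
    base_levels: dict = field(default_factory=_default_base_levels)
    covariate_effects: dict = field(default_factory=_default_covariate_effects)
    plateau_fluids: tuple[str, ...] = ("plasma_nfl",)
    sd_family_intercept: float = 0.05
    sd_subject_intercept: float = 0.08
    sd_subject_slope: float = 0.010
    sd_residual: float = 0.05
    replicate_cv_mean: float = 0.05
    onset_sd_years: float = 2.0
    imaging_coupling: float = -2000.0  # mm^3/yr per (log10 CSF NfL)/yr, symptomatic only
    dropout_prob: float = 0.05
    reverter_prob: float = 0.02
    n_outliers: int = 3
    nc_cdr_positive_prob: float = 0.04
    p_single_replicate: float = 0.01
    p_high_cv: float = 0.02
    p_missing_fluid: float = 0.05
    p_missing_imaging: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "sd_family_intercept",
            "sd_subject_intercept",
            "sd_subject_slope",
            "sd_residual",
            "replicate_cv_mean",
            "onset_sd_years",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_carriers < 0 or self.n_noncarriers < 0:
            raise ConfigError("n_carriers and n_noncarriers must be nonnegative")
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        if self.n_families > self.n_carriers + self.n_noncarriers:
            raise ConfigError(
                "n_families must not exceed the number of participants "
                f"({self.n_families} > {self.n_carriers + self.n_noncarriers})"
            )
        lo, hi = self.eyo_baseline_range
        if not lo < hi:
            raise ConfigError(f"eyo_baseline_range must be ordered, got {(lo, hi)}")
        a, b = self.n_visits_range
        if not (1 <= a <= b):
            raise ConfigError(f"n_visits_range must satisfy 1 <= lo <= hi, got {(a, b)}")
        for p in ("dropout_prob", "reverter_prob", "nc_cdr_positive_prob",
                  "p_single_replicate", "p_high_cv", "p_missing_fluid",
                  "p_missing_imaging"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{p} must be in [0, 1], got {v}")
        for fluid in FLUIDS:
            if fluid not in self.carrier_slope_params:
                raise ConfigError(f"carrier_slope_params missing fluid {fluid!r}")


def disease_rate(eyo, k, divergence_eyo, plateau_eyo=None):
    """d/d(eyo) of the carrier disease component (log10 units per year)."""
    e = np.asarray(eyo, dtype=float)
    r = k * np.clip(e - divergence_eyo, 0.0, None)
    if plateau_eyo is not None:
        r = np.minimum(r, k * max(plateau_eyo - divergence_eyo, 0.0))
    return r


def disease_level(eyo, k, divergence_eyo, plateau_eyo=None):
    """Carrier disease component D(eyo): exact integral of the rate ramp."""
    e = np.asarray(eyo, dtype=float)
    d = divergence_eyo
    if plateau_eyo is None:
        return 0.5 * k * np.clip(e - d, 0.0, None) ** 2
    p = max(plateau_eyo, d)
    rising = 0.5 * k * np.clip(np.minimum(e, p) - d, 0.0, None) ** 2
    plateau = k * (p - d) * np.clip(e - p, 0.0, None)
    return rising + plateau


@dataclass
class SimTruth:
    """Generating parameters plus realized per-subject effects.

    Consumed only by recovery tests and reporting, never by inference code.
    """

    config: SimConfig
    subjects: dict  # pid -> realized effects, windows, true slopes
    variant_onsets: dict  # variant_id -> true mean onset age

    def subject(self, participant_id: str) -> dict:
        return self.subjects[participant_id]


def _mean_log10(cfg: SimConfig, fluid: str, carrier: bool, age, male, bmi, eyo):
    eff = cfg.covariate_effects[fluid]
    m = (
        cfg.base_levels[fluid]
        + eff["age"] * (np.asarray(age, float) - _AGE_REF)
        + eff["sex_male"] * male
        + eff["bmi"] * (bmi - _BMI_REF)
    )
    if carrier:
        plateau = cfg.true_plateau_eyo if fluid in cfg.plateau_fluids else None
        m = m + disease_level(
            eyo, cfg.carrier_slope_params[fluid], cfg.true_divergence_eyo, plateau
        )
    return m


def _replicate_pair(rng, value, cv):
    """Duplicate assay replicates with multiplicative lognormal noise at CV=cv."""
    if cv <= 0:
        return value, value
    s = np.sqrt(np.log1p(cv**2))
    z = rng.standard_normal(2)
    return tuple(value * np.exp(s * zi - 0.5 * s**2) for zi in z)


def generate_cohort(config: SimConfig):
    """Generate (participants, visits, SimTruth) for one synthetic cohort.

    Identical config (including seed) yields byte-identical tables.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_total = cfg.n_carriers + cfg.n_noncarriers

    # --- families and variants -------------------------------------------
    genes = rng.choice(["PSEN1", "APP", "PSEN2"], size=cfg.n_families, p=[0.76, 0.16, 0.08])
    onset_means = np.clip(rng.normal(46.0, 7.0, cfg.n_families), 30.0, 62.0)
    variant_ids = [f"VAR{i:03d}" for i in range(cfg.n_families)]
    variant_onsets = {v: float(m) for v, m in zip(variant_ids, onset_means)}

    # participant-level draws
    status = np.array(["carrier"] * cfg.n_carriers + ["noncarrier"] * cfg.n_noncarriers)
    rng.shuffle(status)
    family_idx = np.arange(n_total) % cfg.n_families
    male = rng.random(n_total) < 0.45
    bmi = np.clip(rng.normal(27.7, 6.0, n_total), 16.0, 55.0)
    eyo0 = rng.uniform(*cfg.eyo_baseline_range, n_total)
    n_visits = rng.integers(cfg.n_visits_range[0], cfg.n_visits_range[1] + 1, n_total)
    outlier_ids = set(rng.choice(n_total, size=min(cfg.n_outliers, n_total), replace=False))

    # family random intercepts per analyte stream
    streams = list(FLUIDS) + ["volume"]
    fam_eff = {s: rng.normal(0.0, cfg.sd_family_intercept, cfg.n_families) for s in FLUIDS}
    fam_eff["volume"] = rng.normal(0.0, 40.0, cfg.n_families)

    participants = []
    visit_rows = []
    subjects = {}

    for i in range(n_total):
        pid = f"P{i:04d}"
        fam = int(family_idx[i])
        fam_id = f"F{fam:03d}"
        variant = variant_ids[fam]
        onset = variant_onsets[variant]
        carrier = status[i] == "carrier"
        age0 = onset + eyo0[i]
        if age0 < 18.0:  # enrol adults only; shift the window later in life
            age0 = 18.0
        base_eyo = age0 - onset

        # realized conversion age: carriers convert near their expected onset
        conv_age = onset + rng.normal(0.0, cfg.onset_sd_years) if carrier else np.inf

        subj_int = {f: rng.normal(0.0, cfg.sd_subject_intercept) for f in FLUIDS}
        subj_slope = {f: rng.normal(0.0, cfg.sd_subject_slope) for f in FLUIDS}

        is_reverter = carrier and rng.random() < cfg.reverter_prob
        nc_cdr_pos = (not carrier) and rng.random() < cfg.nc_cdr_positive_prob

        # --- visit schedule: 2-yearly, annual once symptomatic ------------
        ages = []
        a = age0
        for _ in range(int(n_visits[i])):
            ages.append(a)
            a += (
                cfg.symptomatic_interval_years
                if (carrier and a >= conv_age)
                else cfg.visit_interval_years
            )
        keep = [True] + [rng.random() >= cfg.dropout_prob for _ in ages[1:]]
        ages = [a for a, k in zip(ages, keep) if k]
        times = [a - ages[0] for a in ages]
        eyos = [a - onset for a in ages]

        # --- CDR sequence --------------------------------------------------
        cdr_seq = []
        for a in ages:
            if is_reverter:
                cdr_seq.append(0.5 if a == ages[0] else 0.0)
            elif carrier:
                since = a - conv_age
                if since < 0:
                    cdr_seq.append(0.0)
                elif since < 3:
                    cdr_seq.append(0.5)
                elif since < 6:
                    cdr_seq.append(1.0)
                else:
                    cdr_seq.append(2.0)
            else:
                cdr_seq.append(0.5 if (nc_cdr_pos and a == ages[0]) else 0.0)
        ever_symptomatic = carrier and any(c > 0 for c in cdr_seq)

        # --- fluid measurements -------------------------------------------
        outlier = i in outlier_ids
        fluid_obs = {}
        for f in FLUIDS:
            rows = []
            for a, e in zip(ages, eyos):
                mean = _mean_log10(cfg, f, carrier, a, male[i], bmi[i], e)
                mean += fam_eff[f][fam] + subj_int[f] + subj_slope[f] * (a - ages[0])
                value = 10.0 ** (mean + rng.normal(0.0, cfg.sd_residual)
                                 if cfg.sd_residual > 0 else mean)
                if outlier:
                    value *= 10.0
                missing = rng.random() < cfg.p_missing_fluid
                single = rng.random() < cfg.p_single_replicate
                high_cv = rng.random() < cfg.p_high_cv
                cv = rng.uniform(0.22, 0.35) if high_cv else cfg.replicate_cv_mean
                r1, r2 = _replicate_pair(rng, value, cv)
                rm1 = rm2 = np.nan
                if f == "csf_nfl" and (high_cv or single):
                    rm1, rm2 = _replicate_pair(rng, value, cfg.replicate_cv_mean)
                rows.append(
                    dict(
                        rep1=np.nan if missing else r1,
                        rep2=np.nan if (missing or single) else r2,
                        rem1=np.nan if missing else rm1,
                        rem2=np.nan if missing else rm2,
                    )
                )
            fluid_obs[f] = rows

        # --- imaging --------------------------------------------------------
        icv = rng.normal(1.45e6, 1.3e5)
        true_csf_slope = _true_window_slope(cfg, "csf_nfl", carrier, times, eyos, subj_slope)
        vol_base = (
            9700.0
            + 0.004 * (icv - 1.45e6)
            + fam_eff["volume"][fam]
            + rng.normal(0.0, 500.0)
            - 40.0 * max(0.0, base_eyo - cfg.true_divergence_eyo) * carrier
        )
        vol_slope = rng.normal(-10.0, 8.0)
        if ever_symptomatic:
            vol_slope += cfg.imaging_coupling * true_csf_slope
        if carrier:
            suvr_base = 1.2 + 2.6 / (1.0 + np.exp(-(base_eyo + 12.0) / 4.0))
            suvr_slope = rng.normal(0.05, 0.03)
        else:
            suvr_base = rng.normal(1.2, 0.15)
            suvr_slope = rng.normal(0.002, 0.010)

        # --- assemble visit rows -------------------------------------------
        for j, (a, t, e, cdr) in enumerate(zip(ages, times, eyos, cdr_seq)):
            mmse = 29.5 - (2.0 * max(0.0, a - conv_age) if carrier else 0.0)
            mmse = float(np.clip(mmse + rng.normal(0.0, 1.0), 0.0, 30.0))
            img_missing = rng.random() < cfg.p_missing_imaging
            row = dict(
                participant_id=pid,
                visit_index=j,
                age_at_visit=round(a, 4),
                time_from_baseline=round(t, 4),
                eyo=round(e, 4),
                cdr_global=cdr,
                mmse=round(mmse, 1),
                icv=round(icv, 1),
            )
            for f in FLUIDS:
                obs = fluid_obs[f][j]
                short = "plasma" if f == "plasma_nfl" else "csf"
                row[f"{short}_nfl_rep1"] = obs["rep1"]
                row[f"{short}_nfl_rep2"] = obs["rep2"]
                if f == "csf_nfl":
                    row["csf_nfl_remeasured_rep1"] = obs["rem1"]
                    row["csf_nfl_remeasured_rep2"] = obs["rem2"]
            if img_missing:
                row["precuneus_volume"] = np.nan
                row["precuneus_pib_suvr"] = np.nan
            else:
                row["precuneus_volume"] = round(
                    vol_base + vol_slope * t + rng.normal(0.0, 60.0), 2
                )
                row["precuneus_pib_suvr"] = round(
                    max(0.8, suvr_base + suvr_slope * t + rng.normal(0.0, 0.05)), 4
                )
            visit_rows.append(row)

        reported = ";".join(
            f"{v:.2f}" for v in (onset - 2.0, onset, onset + 2.0)
        )  # mean equals the true variant onset
        participants.append(
            dict(
                participant_id=pid,
                family_id=fam_id,
                mutation_status=status[i],
                gene=genes[fam] if carrier else "none",
                variant_id=variant,
                variant_reported_onsets=reported,
                variant_pathogenic=True,
                sex="male" if male[i] else "female",
                baseline_age=round(ages[0], 4),
                baseline_bmi=round(bmi[i], 2),
                parental_onset_age=round(onset + rng.normal(0.0, 3.0), 2),
                competing_disorder_flag=outlier,
            )
        )

        subjects[pid] = dict(
            family_id=fam_id,
            mutation_status=status[i],
            expected_onset_age=onset,
            conversion_age=None if not np.isfinite(conv_age) else float(conv_age),
            ever_symptomatic=bool(ever_symptomatic),
            baseline_eyo=float(base_eyo),
            visit_times=[float(t) for t in times],
            visit_eyos=[float(e) for e in eyos],
            family_effects={f: float(fam_eff[f][fam]) for f in FLUIDS},
            subject_intercepts={f: float(subj_int[f]) for f in FLUIDS},
            subject_slopes={f: float(subj_slope[f]) for f in FLUIDS},
            true_fluid_slopes={
                f: _true_window_slope(cfg, f, carrier, times, eyos, subj_slope)
                for f in FLUIDS
            },
            true_volume_slope=float(vol_slope),
            true_suvr_slope=float(suvr_slope),
            icv=float(icv),
        )

    participants = pd.DataFrame(participants)
    visits = pd.DataFrame(visit_rows)
    truth = SimTruth(config=cfg, subjects=subjects, variant_onsets=variant_onsets)
    return participants, visits, truth


def _true_window_slope(cfg, fluid, carrier, times, eyos, subj_slope):
    """True annualized log10 slope over the observed window (noise-free).

    Window average of the generating rate: subject random slope + age trend +
    (for carriers) the disease-component increment divided by elapsed time.
    Single-visit subjects get the instantaneous rate at their only visit.
    """
    age_coef = cfg.covariate_effects[fluid]["age"]
    k = cfg.carrier_slope_params[fluid]
    plateau = cfg.true_plateau_eyo if fluid in cfg.plateau_fluids else None
    base = subj_slope[fluid] + age_coef
    if not carrier:
        return float(base)
    if len(times) < 2:
        return float(base + disease_rate(eyos[0], k, cfg.true_divergence_eyo, plateau))
    d0 = disease_level(eyos[0], k, cfg.true_divergence_eyo, plateau)
    d1 = disease_level(eyos[-1], k, cfg.true_divergence_eyo, plateau)
    return float(base + (d1 - d0) / (times[-1] - times[0]))


def truth_slopes(truth: SimTruth, fluid: str) -> pd.DataFrame:
    """Per-subject true annualized slopes (log10 units/year) for one fluid."""
    if fluid not in FLUIDS:
        raise ConfigError(f"unknown fluid {fluid!r}; expected one of {FLUIDS}")
    rows = [
        dict(participant_id=pid, true_slope=rec["true_fluid_slopes"][fluid])
        for pid, rec in truth.subjects.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plain-text serialization


def write_cohort(outdir, participants, visits, truth):
    """Write participants.csv, visits.csv and truth.yaml under ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    participants.to_csv(os.path.join(outdir, "participants.csv"), index=False)
    visits.to_csv(os.path.join(outdir, "visits.csv"), index=False)
    doc = dict(
        config=dataclasses.asdict(truth.config),
        variant_onsets=truth.variant_onsets,
        subjects=truth.subjects,
    )
    with open(os.path.join(outdir, "truth.yaml"), "w") as fh:
        yaml.safe_dump(_plain(doc), fh, sort_keys=True)


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cfg_d = doc["config"]
    for key in ("n_visits_range", "eyo_baseline_range", "plateau_fluids"):
        if key in cfg_d and isinstance(cfg_d[key], list):
            cfg_d[key] = tuple(cfg_d[key])
    return SimTruth(
        config=SimConfig(**cfg_d),
        subjects=doc["subjects"],
        variant_onsets=doc["variant_onsets"],
    )


def _plain(obj):
    """Recursively convert numpy scalars/containers to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
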