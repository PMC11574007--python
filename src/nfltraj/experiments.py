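"""Replication experiments: parameter-recovery studies at fixed conditions.

Each function simulates cohorts (or analyte streams) from the generator at
documented study conditions, runs the corresponding analysis stage, and
returns the recovered quantities. They are used by the acceptance script and
the acceptance test suite; sizes are chosen so a full run completes on one
CPU in minutes (see the methods note for the rationale behind each setting).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import qc, staging, trajectory
from .imaging import adjust_volume_for_icv, fit_imaging_coupling
from .pipeline import _analysis_frame
from .segmented import BreakpointFit, detect_bifurcation, segmented_multistart
from .simulate import SimConfig, disease_rate, generate_cohort
from .slopes import compare_groups, extract_subject_slopes

__all__ = [
    "divergence_recovery",
    "plateau_recovery",
    "imaging_coupling_recovery",
    "fwer_null_calibration",
    "segmented_oracle_agreement",
]

# Low-noise recovery conditions for the divergence study: chosen by a power
# analysis (a quadratic-onset divergence with ramp k becomes detectable
# ~sqrt(4*SE_diff/k) years late; a <=3-year lag at n=400 requires a total
# between+within SD of ~0.024 log10 units).
_DIVERGENCE_NOISE = dict(sd_residual=0.015, sd_family_intercept=0.010,
                         sd_subject_intercept=0.015)

_SAMPLER = trajectory.SamplerSettings(steps=2500, burn=1000, thin=3)


def _clean(**kw) -> SimConfig:
    return SimConfig(replicate_cv_mean=0.0, n_outliers=0, reverter_prob=0.0,
                     p_high_cv=0.0, p_single_replicate=0.0, p_missing_fluid=0.0,
                     **kw)


def divergence_recovery(seeds, null: bool = False):
    """Recover the first persistent divergence EYO from a 400-person cohort.

    True divergence at EYO -20 (or no carrier effect at all under the null);
    carrier/non-carrier split mirrors the 355:212 cohort ratio.
    """
    out = []
    for seed in seeds:
        kw = dict(n_carriers=235, n_noncarriers=165, n_families=100,
                  seed=int(seed), **_DIVERGENCE_NOISE)
        if null:
            kw["carrier_slope_params"] = {"plasma_nfl": 0.0, "csf_nfl": 0.0}
        participants, visits, _ = generate_cohort(_clean(**kw))
        visits = staging.add_eyo(participants, visits)
        participants, visits, _ = staging.apply_exclusions(participants, visits)
        visits = qc.finalize_visits(visits)
        frame = _analysis_frame(participants, visits)
        fit = trajectory.fit_trajectory_model(
            frame, "log10_csf_nfl", sampler=_SAMPLER, seed=int(seed))
        div = trajectory.divergence_point(fit, force=not fit.converged)
        out.append(div.first_persistent_divergence_eyo)
    return out


def plateau_recovery(seeds, fluid: str = "plasma_nfl", n: int = 150):
    """Detect the plasma rate plateau from rate-vs-EYO values.

    Rates follow the generator's disease-rate ramp for the requested fluid
    (plasma plateaus at EYO +3.6, CSF keeps rising), observed with the
    default between-subject slope scatter over a symptomatic-bracketing EYO
    window (-5 to +12 years).
    """
    cfg = SimConfig()
    k = cfg.carrier_slope_params[fluid]
    plateau = cfg.true_plateau_eyo if fluid in cfg.plateau_fluids else None
    results: list[BreakpointFit | None] = []
    for seed in seeds:
        rng = np.random.default_rng(int(seed))
        eyo = rng.uniform(-5.0, 12.0, n)
        rate = disease_rate(eyo, k, cfg.true_divergence_eyo, plateau)
        age_trend = cfg.covariate_effects[fluid]["age"]
        y = age_trend + rate + rng.normal(0.0, cfg.sd_subject_slope, n)
        results.append(detect_bifurcation(eyo, y))
    return results


def imaging_coupling_recovery(seeds):
    """Recover the volume-atrophy coupling and the PiB null in symptomatic MC.

    Symptomatic-stage cohorts (~60 symptomatic carriers with imaging) are
    generated with the default coupling of -2000 mm^3/yr per unit CSF-NfL
    slope and PiB accumulation independent of NfL.
    """
    out = []
    for seed in seeds:
        cfg = SimConfig(n_carriers=90, n_noncarriers=50, n_families=35,
                        seed=int(seed), eyo_baseline_range=(-5.0, 8.0),
                        n_visits_range=(3, 5))
        participants, visits, _ = generate_cohort(cfg)
        visits = staging.add_eyo(participants, visits)
        participants, visits, _ = staging.apply_exclusions(participants, visits)
        visits = qc.finalize_visits(visits)
        stages = staging.stage_table(participants, visits)
        sym = set(stages.loc[stages["stage"].isin(
            ["symptomatic_MC", "converter_MC"]), "participant_id"])
        nc = set(participants.loc[
            participants["mutation_status"] == "noncarrier", "participant_id"])
        ref = visits["participant_id"].isin(nc).to_numpy()
        visits = visits.assign(vol_adj=adjust_volume_for_icv(
            visits["precuneus_volume"], visits["icv"], ref))
        slopes = extract_subject_slopes(visits, "csf_nfl", participants)
        sub = slopes[slopes["participant_id"].isin(sym)]
        sub_visits = visits[visits["participant_id"].isin(sym)]
        vol = fit_imaging_coupling(sub_visits, sub, participants, "vol_adj",
                                   "symptomatic_MC")
        pib = fit_imaging_coupling(sub_visits, sub, participants,
                                   "precuneus_pib_suvr", "symptomatic_MC")
        out.append((vol, pib))
    return out


def fwer_null_calibration(n_replicates: int = 200, seed: int = 0,
                          alpha: float = 0.05) -> float:
    """Family-wise error of the Holm-adjusted group contrasts under the null.

    Group sizes mirror the published rate-of-change analysis (NC 88,
    presymptomatic 79, converters 13, symptomatic 48); all groups share one
    generating distribution. Returns the fraction of replicates with any
    adjusted p below alpha.
    """
    sizes = {"NC": 88, "presymptomatic_MC": 79, "converter_MC": 13,
             "symptomatic_MC": 48}
    root = np.random.default_rng(int(seed))
    false_hits = 0
    for _ in range(n_replicates):
        rng = np.random.default_rng(root.integers(2**31 - 1))
        rows, stage_rows, part_rows = [], [], []
        i = 0
        for stage, n in sizes.items():
            for _ in range(n):
                pid = f"P{i:04d}"
                rows.append(dict(participant_id=pid, analyte="csf_nfl",
                                 annualized_slope=rng.normal(0.02, 0.01),
                                 n_visits_used=3))
                stage_rows.append(dict(participant_id=pid, stage=stage))
                part_rows.append(dict(
                    participant_id=pid, family_id=f"F{i % 60}",
                    baseline_age=rng.normal(40, 10),
                    baseline_bmi=rng.normal(27, 5),
                    sex=("male" if rng.random() < 0.45 else "female")))
                i += 1
        comp = compare_groups(pd.DataFrame(rows), pd.DataFrame(stage_rows),
                              pd.DataFrame(part_rows))
        false_hits += bool((comp["p_adjusted"] < alpha).any())
    return false_hits / n_replicates


def segmented_oracle_agreement(seeds, n: int = 200, resolution: float = 0.01):
    """Max |psi difference| between the iterative fit and a profile-RSS grid."""
    diffs = []
    for seed in seeds:
        rng = np.random.default_rng(int(seed))
        x = rng.uniform(-5.0, 10.0, n)
        y = (0.2 * np.minimum(x, 3.0) + 1.1 * np.clip(x - 3.0, 0.0, None)
             + rng.normal(0.0, 0.3, n))
        fit = segmented_multistart(x, y)
        lo, hi = np.quantile(x, [0.05, 0.95])
        ones = np.ones_like(x)

        def profile_argmin(grid):
            best, best_psi = np.inf, None
            for psi in grid:
                X = np.column_stack([ones, x, np.clip(x - psi, 0.0, None)])
                coef, *_ = np.linalg.lstsq(X, y, rcond=None)
                rss = float(np.sum((y - X @ coef) ** 2))
                if rss < best:
                    best, best_psi = rss, psi
            return best_psi

        # exhaustive coarse scan followed by local refinement, so the oracle
        # itself is accurate well below the comparison resolution
        coarse = profile_argmin(np.arange(lo, hi, resolution))
        fine = profile_argmin(np.arange(coarse - resolution, coarse + resolution,
                                        resolution / 10.0))
        diffs.append(abs(fit.psi - fine))
    return diffs
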