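"""End-to-end orchestration: simulate -> stage/QC -> fit -> compare -> report.

Every run writes a deterministic directory layout:

    tables/   delimited-text outputs (cohort, stages, slopes, comparisons)
    fits/     model summaries (trajectory coefficients, divergence, breakpoints)
    report.txt  structured text report
    manifest.yaml  package version, config hash, seed
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import gam, imaging, qc, report, segmented, slopes, staging, trajectory
from .errors import NflTrajError
from .simulate import SimConfig, generate_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline"]

ALL_STAGES = ("simulate", "stage", "qc", "trajectory", "slopes", "compare",
              "breakpoint", "imaging", "report")


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    input_dir: str | None = None      # read participants.csv/visits.csv instead of simulating
    stages: tuple[str, ...] = ALL_STAGES
    fluids: tuple[str, ...] = ("plasma_nfl", "csf_nfl")
    seed: int = 0
    outdir: str = "nfltraj_run"
    mcmc_walkers: int = 16
    mcmc_steps: int = 2500
    mcmc_burn: int = 1000
    mcmc_thin: int = 3

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise NflTrajError(f"unknown pipeline stages {sorted(unknown)}")
        if self.input_dir is None and "simulate" not in self.stages:
            raise NflTrajError("either enable the simulate stage or provide input_dir")

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> str:
    cfg = config
    cfg.validate()
    out = cfg.outdir
    tables = os.path.join(out, "tables")
    fits = os.path.join(out, "fits")
    os.makedirs(tables, exist_ok=True)
    os.makedirs(fits, exist_ok=True)
    lines = [f"nfltraj {__version__} run (seed {cfg.seed})", ""]

    # --- data ---------------------------------------------------------------
    if "simulate" in cfg.stages:
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        participants, visits, truth = generate_cohort(sim)
        write_cohort(tables, participants, visits, truth)
    else:
        participants = pd.read_csv(os.path.join(cfg.input_dir, "participants.csv"))
        visits = pd.read_csv(os.path.join(cfg.input_dir, "visits.csv"))

    # --- staging -------------------------------------------------------------
    if "stage" in cfg.stages:
        visits = staging.add_eyo(participants, visits)
        participants, visits, excl_log = staging.apply_exclusions(participants, visits)
        stages_df = staging.stage_table(participants, visits)
        excl_log.to_csv(os.path.join(tables, "exclusion_log.csv"), index=False)
        stages_df.to_csv(os.path.join(tables, "stages.csv"), index=False)
        lines += ["Exclusions applied: "
                  f"{len(excl_log)} log rows", ""]
    else:
        stages_df = None

    # --- QC -------------------------------------------------------------------
    if "qc" in cfg.stages:
        replicates = qc.visits_to_replicates(visits)
        qc_table = qc.qc_pipeline(replicates)
        qc_table.to_csv(os.path.join(tables, "qc_records.csv"), index=False)
        visits = qc.finalize_visits(visits)
        visits.to_csv(os.path.join(tables, "visits_final.csv"), index=False)
        lines += ["QC summary:", yaml.safe_dump(qc.qc_summary(qc_table)), ""]

    analysis = _analysis_frame(participants, visits)

    # --- Bayesian trajectory fits --------------------------------------------
    if "trajectory" in cfg.stages:
        sampler = trajectory.SamplerSettings(
            walkers=cfg.mcmc_walkers, steps=cfg.mcmc_steps, burn=cfg.mcmc_burn,
            thin=cfg.mcmc_thin)
        for fluid in cfg.fluids:
            colname = f"log10_{fluid}"
            fit = trajectory.fit_trajectory_model(
                analysis, colname, sampler=sampler, seed=cfg.seed)
            div = trajectory.divergence_point(fit, force=not fit.converged)
            fit.coefficient_table().to_csv(
                os.path.join(fits, f"trajectory_{fluid}.csv"), index=False)
            div.difference_curve.to_csv(
                os.path.join(fits, f"difference_curve_{fluid}.csv"), index=False)
            lines.append(
                f"{fluid}: first divergence EYO = {div.first_divergence_eyo} "
                f"(persistent from {div.first_persistent_divergence_eyo}; "
                f"converged={fit.converged})")
            alt = gam.fit_penalized_spline_alternative(analysis, colname)
            lines.append(f"{fluid}: penalized-spline divergence EYO = {alt.divergence_eyo}")
        lines.append("")

    # --- slopes, group comparisons, ratio ------------------------------------
    slope_tables = {}
    if "slopes" in cfg.stages:
        for fluid in cfg.fluids:
            tab = slopes.extract_subject_slopes(visits, fluid, participants)
            slope_tables[fluid] = tab
            tab.to_csv(os.path.join(tables, f"slopes_{fluid}.csv"), index=False)

    if "compare" in cfg.stages and stages_df is not None and slope_tables:
        for fluid, tab in slope_tables.items():
            comp = slopes.compare_groups(tab, stages_df, participants)
            comp.to_csv(os.path.join(tables, f"group_comparison_{fluid}.csv"), index=False)
            lines += [f"Group comparison ({fluid}):", comp.to_string(index=False), ""]
        ratio = slopes.baseline_ratio_table(visits)
        comp = slopes.compare_groups(ratio, stages_df, participants)
        comp.to_csv(os.path.join(tables, "group_comparison_ratio.csv"), index=False)
        lines += ["Group comparison (plasma/CSF ratio):", comp.to_string(index=False), ""]

    # --- breakpoints ----------------------------------------------------------
    if "breakpoint" in cfg.stages and slope_tables:
        base_eyo = analysis.set_index("participant_id")["eyo"]
        for fluid, tab in slope_tables.items():
            carriers = participants.loc[
                participants["mutation_status"] == "carrier", "participant_id"]
            sub = tab[tab["participant_id"].isin(carriers)]
            x = sub["participant_id"].map(base_eyo).to_numpy(float)
            y = sub["annualized_slope"].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            fit = segmented.detect_bifurcation(x[ok], y[ok])
            if fit is None:
                lines.append(f"{fluid}: no bifurcation point detected")
            else:
                lines.append(
                    f"{fluid}: bifurcation at EYO {fit.psi:+.2f} "
                    f"(slopes {fit.left_slope:.4f} -> {fit.right_slope:.4f}, "
                    f"p={fit.davies_p:.3g})")
        lines.append("")

    # --- imaging coupling ------------------------------------------------------
    if "imaging" in cfg.stages and slope_tables and stages_df is not None:
        img = visits.copy()
        base = _analysis_frame(participants, visits)
        nc_ids = set(participants.loc[
            participants["mutation_status"] == "noncarrier", "participant_id"])
        ref_mask = img["participant_id"].isin(nc_ids).to_numpy()
        with np.errstate(invalid="ignore"):
            img["precuneus_volume_adj"] = imaging.adjust_volume_for_icv(
                img["precuneus_volume"], img["icv"], ref_mask)
        sym = set(stages_df.loc[stages_df["stage"].isin(
            ["symptomatic_MC", "converter_MC"]), "participant_id"])
        rows = []
        for fluid, tab in slope_tables.items():
            for label, ids in (("symptomatic_MC", sym),):
                sub_img = img[img["participant_id"].isin(ids)]
                sub_slopes = tab[tab["participant_id"].isin(ids)]
                for outcome in ("precuneus_volume_adj", "precuneus_pib_suvr"):
                    try:
                        res = imaging.fit_imaging_coupling(
                            sub_img, sub_slopes, participants, outcome, label)
                    except NflTrajError as exc:
                        lines.append(f"imaging {fluid}/{outcome}/{label}: {exc}")
                        continue
                    rows.append(dataclasses.asdict(res))
        if rows:
            pd.DataFrame(rows).to_csv(
                os.path.join(tables, "imaging_coupling.csv"), index=False)
            lines += ["Imaging coupling:", pd.DataFrame(rows).to_string(index=False), ""]

    # --- report ----------------------------------------------------------------
    if "report" in cfg.stages:
        desc = report.descriptive_table(participants, visits)
        desc.to_csv(os.path.join(tables, "descriptives.csv"), index=False)
        lines += ["Baseline characteristics:", desc.to_string(index=False), ""]

    with open(os.path.join(out, "report.txt"), "w") as fh:
        fh.write("\n".join(str(x) for x in lines))
    manifest = dict(version=__version__, seed=cfg.seed, config_hash=cfg.config_hash(),
                    stages=list(cfg.stages))
    with open(os.path.join(out, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh)
    return out


def _analysis_frame(participants: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    """Baseline analysis table: one row per participant with model columns."""
    base = visits.sort_values(["participant_id", "visit_index"]).groupby(
        "participant_id", as_index=False).first()
    df = participants.merge(base, on="participant_id", how="inner")
    out = pd.DataFrame(dict(
        participant_id=df["participant_id"],
        family_id=df["family_id"],
        status=(df["mutation_status"] == "carrier").astype(float),
        eyo=df["eyo"] if "eyo" in df.columns else np.nan,
        age=df["baseline_age"],
        sex=(df["sex"] == "male").astype(float),
        bmi=df["baseline_bmi"],
    ))
    for col in ("log10_plasma_nfl", "log10_csf_nfl", "plasma_nfl", "csf_nfl"):
        if col in df.columns:
            out[col] = df[col]
    return out
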