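"""Synthetic cohort generator: determinism, bookkeeping, noiseless exactness."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from nfltraj import qc
from nfltraj.errors import ConfigError
from nfltraj.simulate import (
    SimConfig,
    _mean_log10,
    _replicate_pair,
    disease_level,
    disease_rate,
    generate_cohort,
    truth_slopes,
)


def test_identical_seed_gives_identical_tables():
    cfg = SimConfig(n_carriers=30, n_noncarriers=20, n_families=10, seed=42)
    p1, v1, _ = generate_cohort(cfg)
    p2, v2, _ = generate_cohort(dataclasses.replace(cfg))
    pd.testing.assert_frame_equal(p1, p2)
    pd.testing.assert_frame_equal(v1, v2)


def test_group_counts_match_config_exactly():
    cfg = SimConfig(n_carriers=355, n_noncarriers=212, n_families=140, seed=0)
    participants, _, _ = generate_cohort(cfg)
    counts = participants["mutation_status"].value_counts()
    assert len(participants) == 567
    assert counts["carrier"] == 355
    assert counts["noncarrier"] == 212


@pytest.mark.parametrize(
    "field,value",
    [
        ("sd_residual", -0.1),
        ("n_families", 0),
        ("eyo_baseline_range", (10.0, -30.0)),
        ("dropout_prob", 1.5),
        ("n_visits_range", (0, 3)),
    ],
)
def test_invalid_config_raises_and_names_field(field, value):
    cfg = dataclasses.replace(SimConfig(), **{field: value})
    with pytest.raises(ConfigError):
        cfg.validate()


def test_too_many_families_rejected():
    with pytest.raises(ConfigError, match="n_families"):
        SimConfig(n_carriers=3, n_noncarriers=2, n_families=10).validate()


def test_noiseless_values_lie_on_generating_curve(noiseless_config):
    participants, visits, _ = generate_cohort(noiseless_config)
    final = qc.finalize_visits(visits)
    idx = participants.set_index("participant_id")
    for _, row in final.iterrows():
        pid = row["participant_id"]
        carrier = idx.loc[pid, "mutation_status"] == "carrier"
        male = float(idx.loc[pid, "sex"] == "male")
        for fluid in ("plasma_nfl", "csf_nfl"):
            mean = _mean_log10(
                noiseless_config, fluid, carrier, row["age_at_visit"], male,
                idx.loc[pid, "baseline_bmi"], row["eyo"],
            )
            # table values are rounded to 4 decimals on the age/EYO axes
            assert np.log10(row[fluid]) == pytest.approx(mean, abs=1e-4)


def test_replicate_cv_converges_to_configured_mean():
    # pooled duplicate CV (root-mean-square of per-pair CVs, the standard
    # assay-QC pooled estimator) converges to the configured mean CV
    rng = np.random.default_rng(123)
    target = 0.05
    pairs = np.array([_replicate_pair(rng, 100.0, target) for _ in range(10_000)])
    cv2 = (pairs[:, 0] - pairs[:, 1]) ** 2 / 2.0 / pairs.mean(axis=1) ** 2
    assert np.sqrt(cv2.mean()) == pytest.approx(target, rel=0.10)


def test_disease_level_is_integral_of_rate():
    # trapezoid integration of the rate ramp reproduces the closed-form level
    k, d, p = 0.0025, -20.0, 3.6
    grid = np.linspace(-30.0, 12.0, 20001)
    rate = disease_rate(grid, k, d, p)
    level = disease_level(grid, k, d, p)
    integral = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2 * np.diff(grid))])
    assert np.allclose(level - level[0], integral, atol=1e-6)


def test_truth_slopes_match_finite_difference_oracle(noiseless_config):
    cfg = dataclasses.replace(noiseless_config, eyo_baseline_range=(-2.0, 6.0),
                              n_visits_range=(3, 3))
    _, visits, truth = generate_cohort(cfg)
    slopes = truth_slopes(truth, "plasma_nfl").set_index("participant_id")["true_slope"]
    for pid, rec in truth.subjects.items():
        times, eyos = rec["visit_times"], rec["visit_eyos"]
        if len(times) < 2:
            continue
        carrier = rec["mutation_status"] == "carrier"
        k = cfg.carrier_slope_params["plasma_nfl"]
        # brute-force finite difference of the generating mean (disease part +
        # age trend; random effects are all zero in this config)
        d0 = disease_level(eyos[0], k, cfg.true_divergence_eyo, cfg.true_plateau_eyo)
        d1 = disease_level(eyos[-1], k, cfg.true_divergence_eyo, cfg.true_plateau_eyo)
        expected = cfg.covariate_effects["plasma_nfl"]["age"]
        if carrier:
            expected += (d1 - d0) / (times[-1] - times[0])
        assert slopes[pid] == pytest.approx(expected, abs=1e-10)


def test_truth_slopes_unknown_fluid_errors(small_cohort):
    *_, truth = small_cohort
    with pytest.raises(ConfigError, match="unknown fluid"):
        truth_slopes(truth, "serum_tau")


def test_missingness_and_outlier_bookkeeping(small_cohort):
    cfg, participants, visits, _ = small_cohort
    assert participants["competing_disorder_flag"].sum() == cfg.n_outliers
    # visit counts bounded by the configured range
    per = visits.groupby("participant_id").size()
    assert per.max() <= cfg.n_visits_range[1]
    assert per.min() >= 1
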