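"""Bayesian spline LMM: calibration, divergence logic, determinism."""

import numpy as np
import pandas as pd
import pytest

from nfltraj.errors import FitError
from nfltraj.splines import SplineSpec, rcs_basis
from nfltraj.trajectory import (
    SamplerSettings,
    TERMS,
    divergence_point,
    fit_trajectory_model,
)

SPEC = SplineSpec((-25.0, -10.0, 5.0))
FAST = SamplerSettings(steps=1200, burn=600, thin=2)

TRUE_BETA = dict(intercept=2.4, status=0.05, eyo_linear=0.004, eyo_cubic=0.01,
                 status_x_linear=0.003, status_x_cubic=0.02,
                 age=0.008, sex=0.05, bmi=-0.004)


def model_data(seed, n=300, beta=TRUE_BETA, sigma_f=0.05, sigma_e=0.05,
               n_families=40):
    """Draw data from the fitted model's own likelihood."""
    rng = np.random.default_rng(seed)
    eyo = rng.uniform(-30, 10, n)
    status = (rng.random(n) < 0.6).astype(float)
    age = 45.0 + eyo + rng.normal(0, 7, n)
    sex = (rng.random(n) < 0.45).astype(float)
    bmi = rng.normal(27.5, 5, n)
    fam = rng.integers(0, n_families, n)
    lin, cub = rcs_basis(eyo, SPEC)
    mean = (beta["intercept"] + beta["status"] * status + beta["eyo_linear"] * lin
            + beta["eyo_cubic"] * cub + beta["status_x_linear"] * status * lin
            + beta["status_x_cubic"] * status * cub + beta["age"] * age
            + beta["sex"] * sex + beta["bmi"] * bmi)
    fam_eff = rng.normal(0, sigma_f, n_families)
    y = mean + fam_eff[fam] + rng.normal(0, sigma_e, n)
    return pd.DataFrame(dict(y=y, eyo=eyo, status=status, age=age, sex=sex,
                             bmi=bmi, family_id=[f"F{f}" for f in fam]))


def _interval(fit, term):
    """95% interval of one non-intercept coefficient on the original scale."""
    j = list(TERMS).index(term)
    orig = fit.beta_flat()[:, j] / fit.col_sds[j]
    return np.percentile(orig, [2.5, 97.5])


def test_posterior_intervals_cover_generating_coefficients():
    """Simulation-based calibration at reduced scale: 95% intervals should
    cover the generating coefficients in the large majority of replicates."""
    terms = [t for t in TERMS if t != "intercept"]
    hits = {t: 0 for t in terms}
    n_rep = 8
    for seed in range(n_rep):
        df = model_data(seed)
        fit = fit_trajectory_model(df, "y", spec=SPEC, sampler=FAST, seed=seed)
        for t in terms:
            lo, hi = _interval(fit, t)
            hits[t] += lo <= TRUE_BETA[t] <= hi
    total = sum(hits.values())
    assert total >= 0.80 * n_rep * len(terms), hits
    assert all(v >= n_rep - 3 for v in hits.values()), hits


def test_null_status_effects_centered_on_zero():
    beta = dict(TRUE_BETA, status=0.0, status_x_linear=0.0, status_x_cubic=0.0)
    covered = 0
    for seed in (11, 12):
        df = model_data(seed, beta=beta)
        fit = fit_trajectory_model(df, "y", spec=SPEC, sampler=FAST, seed=seed)
        for t in ("status", "status_x_linear", "status_x_cubic"):
            lo, hi = _interval(fit, t)
            covered += lo <= 0.0 <= hi
    assert covered >= 5  # 6 intervals, allow one unlucky miss


def test_family_sd_posterior_orders_with_generation():
    meds = {}
    for sigma_f in (0.0, 0.3):
        vals = []
        for seed in (21, 22):
            df = model_data(seed, sigma_f=sigma_f)
            fit = fit_trajectory_model(df, "y", spec=SPEC, sampler=FAST, seed=seed)
            vals.append(float(np.median(fit.sigma_family)))
        meds[sigma_f] = np.mean(vals)
    assert meds[0.3] > meds[0.0]


def test_seed_determinism():
    df = model_data(5)
    f1 = fit_trajectory_model(df, "y", spec=SPEC, sampler=FAST, seed=9)
    f2 = fit_trajectory_model(df, "y", spec=SPEC, sampler=FAST, seed=9)
    assert np.array_equal(f1.beta, f2.beta)
    assert np.array_equal(f1.sigma_resid, f2.sigma_resid)


def test_uniform_separation_detected_at_first_grid_point():
    beta = dict(TRUE_BETA, status=0.5, status_x_linear=0.0, status_x_cubic=0.0)
    df = model_data(31, beta=beta, sigma_e=0.03, sigma_f=0.0)
    fit = fit_trajectory_model(df, "y", spec=SPEC, sampler=FAST, seed=31)
    div = divergence_point(fit, force=True)
    assert div.first_divergence_eyo == div.difference_curve["eyo"].iloc[0]
    assert div.persistence_flag


def test_divergence_monotone_in_effect_size():
    def df_with_scale(c, seed=41):
        rng = np.random.default_rng(seed)
        base = model_data(seed, beta=dict(TRUE_BETA, status=0.0,
                                          status_x_linear=0.0, status_x_cubic=0.0))
        ramp = c * 0.002 * np.clip(base["eyo"] + 20.0, 0.0, None) ** 2 / 10.0
        out = base.copy()
        out["y"] = out["y"] + out["status"] * ramp
        return out

    detected = {}
    for c in (1.0, 3.0):
        df = df_with_scale(c)
        fit = fit_trajectory_model(df, "y", spec=SPEC, sampler=FAST, seed=41)
        div = divergence_point(fit, force=True)
        detected[c] = div.first_persistent_divergence_eyo
    assert detected[3.0] is not None
    if detected[1.0] is not None:
        assert detected[3.0] <= detected[1.0]


def test_difference_curve_invariant_to_covariate_recentering():
    df = model_data(51)
    fit1 = fit_trajectory_model(df, "y", spec=SPEC, sampler=FAST, seed=3)
    shifted = df.assign(age=df["age"] + 10.0, bmi=df["bmi"] - 5.0)
    fit2 = fit_trajectory_model(shifted, "y", spec=SPEC, sampler=FAST, seed=3)
    d1 = divergence_point(fit1, force=True).difference_curve
    d2 = divergence_point(fit2, force=True).difference_curve
    assert np.allclose(d1["median"], d2["median"], atol=1e-10)
    assert np.allclose(d1["lo"], d2["lo"], atol=1e-10)


def test_flagged_fit_refused_without_force():
    df = model_data(61)
    tiny = SamplerSettings(steps=60, burn=30, thin=1)
    with pytest.warns(UserWarning, match="post-warmup"):
        fit = fit_trajectory_model(df, "y", spec=SPEC, sampler=tiny, seed=1)
    fit.converged = False  # exercise the refusal contract deterministically
    with pytest.raises(FitError):
        divergence_point(fit)
    assert divergence_point(fit, force=True).difference_curve is not None


def test_design_adds_exactly_two_eyo_columns():
    assert [t for t in TERMS if t.startswith("eyo_")] == ["eyo_linear", "eyo_cubic"]
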