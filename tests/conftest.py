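import pytest

from nfltraj import qc, staging
from nfltraj.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest noisy cohort shared by tests that only need realistic structure."""
    cfg = SimConfig(n_carriers=80, n_noncarriers=60, n_families=35, seed=7)
    participants, visits, truth = generate_cohort(cfg)
    return cfg, participants, visits, truth


@pytest.fixture(scope="session")
def staged_cohort(small_cohort):
    """The small cohort after EYO staging, exclusions, and assay QC."""
    _, participants, visits, _ = small_cohort
    visits = staging.add_eyo(participants, visits)
    participants, visits, log = staging.apply_exclusions(participants, visits)
    visits = qc.finalize_visits(visits)
    stages = staging.stage_table(participants, visits)
    return participants, visits, stages, log


@pytest.fixture(scope="session")
def noiseless_config():
    return SimConfig(
        n_carriers=12, n_noncarriers=10, n_families=6, seed=1,
        sd_residual=0.0, replicate_cv_mean=0.0, sd_family_intercept=0.0,
        sd_subject_intercept=0.0, sd_subject_slope=0.0,
        p_high_cv=0.0, p_single_replicate=0.0, p_missing_fluid=0.0,
        n_outliers=0, dropout_prob=0.0, reverter_prob=0.0,
        nc_cdr_positive_prob=0.0,
    )
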