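import pytest

from nsclc_cea.patients import PatientProfile, generate_patients
from nsclc_cea.runner import run_cea
from nsclc_cea.simulate import simulate_cohort
from nsclc_cea.synthetic import make_country_config, make_trial_bundle

MASTER_SEED = 0


@pytest.fixture(scope="session")
def us_config():
    return make_country_config("US")


@pytest.fixture(scope="session")
def us_bundle():
    return make_trial_bundle("us_base", seed=MASTER_SEED)


@pytest.fixture(scope="session")
def female_base_case():
    # US base-case female: 77.5 kg, BSA 1.82 m^2, creatinine 0.96, age 64
    return PatientProfile(
        sex="female",
        weight=77.5,
        bsa=1.82,
        serum_creatinine=0.96,
        age=64,
        histology="nonsquamous",
        pdl1="tps_ge1",
        egfr_mutant=False,
        alk_rearranged=False,
    )


@pytest.fixture(scope="session")
def us_base_traces(us_bundle):
    """Full-size base-case traces shared by simulation and outcome tests."""
    patients = generate_patients(1000, us_bundle.priors, seed=MASTER_SEED)
    traces = simulate_cohort(
        patients, us_bundle.arm_models, us_bundle.config, horizon_cycles=120, seed=MASTER_SEED
    )
    return patients, traces


@pytest.fixture(scope="session")
def us_base_result(us_bundle):
    """Full base-case CEA summary (1000 patients, bootstrap CIs)."""
    return run_cea(us_bundle, n_patients=1000, horizon_cycles=120, seed=MASTER_SEED, n_boot=500)
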