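import pytest

from tgctprs import cli, cohort_sim, prs_model

# Study-condition cohort for the empirical oracles: the size at which the
# rank AUC is expected to pin the analytic value to ~0.01.
COHORT_N = 500_000
GENOTYPE_SEED = 1
LABEL_SEED = 2
BASELINE_RISK = 0.005


@pytest.fixture(scope="session")
def panel():
    return prs_model.load_snp_panel(cli.default_panel_path())


@pytest.fixture(scope="session")
def model(panel):
    return prs_model.build_model(panel)


@pytest.fixture(scope="session")
def labelled_cohort(panel, model):
    cohort = cohort_sim.simulate_genotypes(panel, COHORT_N, GENOTYPE_SEED)
    return cohort_sim.assign_case_status(cohort, model, BASELINE_RISK, LABEL_SEED)
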