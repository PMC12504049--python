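import pandas as pd
import pytest

from ftdprog.cohort import (LongitudinalConfig, debm_cohort_config,
                            default_cohort_config, generate_cohort,
                            generate_longitudinal)
from ftdprog.experiments import run_debm_on_cohort


@pytest.fixture(scope="session")
def grn_cohort() -> pd.DataFrame:
    """GRN carriers + controls (480 subjects, 9 biomarkers) at defaults."""
    return generate_cohort(debm_cohort_config(seed=11))


@pytest.fixture(scope="session")
def debm_results(grn_cohort):
    """(table, fits, P, ordering) of the full DEBM pass on grn_cohort."""
    return run_debm_on_cohort(grn_cohort, seed=11)


@pytest.fixture(scope="session")
def full_cohort() -> pd.DataFrame:
    """Full study population (763 subjects, all genotype cells)."""
    return generate_cohort(default_cohort_config(seed=7))


@pytest.fixture(scope="session")
def longitudinal_cohort() -> pd.DataFrame:
    """83 GRN carriers with 3 visits plus their source baseline cohort."""
    base = generate_cohort(debm_cohort_config(seed=13))
    cfg = debm_cohort_config(seed=13)
    from ftdprog.cohort import CohortConfig
    full = CohortConfig(group_sizes=cfg.group_sizes, seed=13)
    baseline = generate_cohort(full)
    return generate_longitudinal(LongitudinalConfig(seed=14), baseline)
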