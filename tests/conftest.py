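import numpy as np
import pytest

from cvdlife.metaprs import GenotypeMatrix
from cvdlife.synthetic import SimulationConfig, simulate_cohort
from cvdlife.transitions import (
    compute_prevalence,
    fit_hrs,
    fit_rates,
    split_person_time,
)
from cvdlife.lifetable import LifeTableInputs


@pytest.fixture(scope="session")
def base_config() -> SimulationConfig:
    """Default study conditions at n=50k (shared across modules)."""
    return SimulationConfig(n=50_000, seed=42)


@pytest.fixture(scope="session")
def cohort50k(base_config):
    return simulate_cohort(base_config)


@pytest.fixture(scope="session")
def ppt50k(cohort50k):
    return split_person_time(cohort50k)


@pytest.fixture(scope="session")
def fitted_inputs(base_config, cohort50k, ppt50k) -> LifeTableInputs:
    """Rates + prevalence + HRs fitted once on the shared cohort."""
    rates = {t: fit_rates(ppt50k, t) for t in (1, 2, 3)}
    prev = compute_prevalence(ppt50k, "genetic_risk")
    hrs = {
        t: fit_hrs(cohort50k, t, "genetic_risk", groups=base_config.group_labels)
        for t in (1, 2, 3)
    }
    return LifeTableInputs(rates=rates, prevalence=prev, hrs=hrs)


@pytest.fixture(scope="session")
def small_panel():
    """Tiny independent-variant genotype panel (n=500, m=60)."""
    from cvdlife.synthetic import simulate_genetics

    dos, variants, summaries, W = simulate_genetics(
        n=500, m_variants=60, n_traits=3, seed=7
    )
    return GenotypeMatrix(dos, variants), summaries, W
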