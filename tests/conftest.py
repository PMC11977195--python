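import numpy as np
import pandas as pd
import pytest

from cortexdev import synthetic_data as sd


@pytest.fixture(scope="session")
def default_effects():
    return sd.default_effect_specs()


@pytest.fixture(scope="session")
def small_cohort():
    """One default cohort at the study design (n=88, all networks/metrics)."""
    return sd.generate_cohort(sd.CohortSpec(seed=11))


@pytest.fixture(scope="session")
def catalog():
    return sd.default_catalog(seed=0)


@pytest.fixture(scope="session")
def multi_region_dataset(catalog):
    return sd.generate_expression(
        sd.ExpressionCohortSpec(dialect="multi_region_rpkm", catalog=catalog, seed=5)
    )


@pytest.fixture(scope="session")
def single_region_dataset(catalog):
    return sd.generate_expression(
        sd.ExpressionCohortSpec(
            dialect="single_region_normalized", n_samples=214,
            age_range=(0.5, 72.0), catalog=catalog, seed=6,
        )
    )


def effect(effects, metric, network):
    """Pull one EffectSpec from the packaged table."""
    for e in effects:
        if e.metric == metric and e.network == network:
            return e
    raise KeyError((metric, network))
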