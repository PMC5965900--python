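import numpy as np
import pytest

from pvnhkit import (
    AnnotatedVariant,
    SimulationConfig,
    simulate_mutation_rate_table,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_trios=200, n_cases=50, n_controls=500, n_genes=100, seed=11
    )


@pytest.fixture(scope="session")
def small_rates(small_config):
    return simulate_mutation_rate_table(small_config)


def make_variant(**overrides):
    """An AnnotatedVariant with clean defaults, overridable per test."""
    qc = {
        "QUAL": 500.0,
        "GQ": 99.0,
        "QD": 10.0,
        "MQ": 60.0,
        "FS": 1.0,
        "HS": 0.5,
        "MQRS": 0.0,
        "RPRS": 0.0,
        "depth": 40,
        "alt_depth": 20,
        "vqsr_pass": True,
    }
    qc.update(overrides.pop("qc", {}))
    base = dict(
        chrom="1",
        pos=1000,
        ref="A",
        alt="T",
        gene="GENE1",
        effect="missense",
        polyphen_humdiv=0.99,
        polyphen_humvar=0.99,
        qc=qc,
        pop_freq={"EVS": 0.0, "ExAC": 0.0},
        cohort_allele_count=1,
        cohort_maf=0.0001,
    )
    base.update(overrides)
    return AnnotatedVariant(**base)


@pytest.fixture
def variant_factory():
    return make_variant
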