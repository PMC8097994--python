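import dataclasses

import pytest

from mirvar.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_reference,
    simulate_variants,
)

# Scaled-down study for fast unit tests; session-scoped because the
# generators are deterministic and read-only in tests.
SMALL = dict(
    n_loci=40,
    n_two_arm_loci=8,
    n_utrs=6,
    sites_per_utr=2,
    n_scan_arms=3,
    n_individuals=100,
    n_background_snps=150,
    n_null_probes=10,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def small_reference(small_cfg):
    return simulate_reference(small_cfg)


@pytest.fixture(scope="session")
def small_variants(small_reference, small_cfg):
    return simulate_variants(small_reference, small_cfg)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def study_reference():
    """Full study-scale reference (370 loci, 409 arms)."""
    return simulate_reference(SimulationConfig(seed=5))


@pytest.fixture(scope="session")
def study_variants(study_reference):
    return simulate_variants(study_reference, SimulationConfig(seed=5))


def replace_cfg(cfg: SimulationConfig, **kw) -> SimulationConfig:
    return dataclasses.replace(cfg, **kw)
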