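import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import famevol as fv
from famevol.simulate import OmegaSpec, SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_alignment():
    """Four short coding sequences with two annotated domains."""
    rows = (
        fv.CodingSequence("At_g1", "ATGAAAGGATGTCCTGAA", species="At"),
        fv.CodingSequence("Al_g1", "ATGAAGGGATGTCCAGAA", species="Al"),
        fv.CodingSequence("Th_g1", "ATGCGTGGTTGTCCAGAG", species="Th"),
        fv.CodingSequence("Th_g2", "ATGCGTGGCTGCCCAGAG", species="Th"),
    )
    domains = (
        fv.DomainAnnotation("N-dom", 1, 3),
        fv.DomainAnnotation("C-dom", 4, 6),
    )
    return fv.CodonAlignment(rows=rows, domains=domains)


@pytest.fixture(scope="session")
def m0_family():
    """An 8-taxon, 500-codon family evolved under a single omega = 0.2."""
    cfg = SimulationConfig(
        seed=7, n_groups=3, loss_spec=("AL3", "Th"),
        region_lengths=(200, 150, 150),
        omega_spec=OmegaSpec(model="M0", omega=0.2),
        rho=0.0, sigma_b=0.0,
    )
    return fv.simulate_alignment(cfg)


@pytest.fixture(scope="session")
def small_mixture_family():
    """A small 8-taxon mixture family for fast model-ladder tests."""
    cfg = SimulationConfig(
        seed=21, n_groups=3, loss_spec=("AL3", "Th"),
        region_lengths=(80, 40, 40),
        omega_spec=OmegaSpec(model="M2a", p0=0.80, p1=0.15, omega0=0.08, omega2=1.0),
        rho=0.0, sigma_b=0.0,
    )
    return fv.simulate_alignment(cfg)


@pytest.fixture(scope="session")
def branch_site_family():
    """An 11-taxon family with 10% of sites under omega2 = 5 on clade AL1."""
    cfg = SimulationConfig(
        seed=11, region_lengths=(200, 150, 150),
        omega_spec=OmegaSpec(
            model="branch-site-A", p0=0.81, p1=0.09, omega0=0.07, omega2=5.0
        ),
        foreground="AL1", rho=0.0, sigma_b=0.0,
    )
    return fv.simulate_alignment(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
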