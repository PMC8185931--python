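from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dmccda import DiseaseOntology, SynthConfig, simulate_instance

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

BENCH = dict(nc=60, nd=20, rank=3, density=0.05, noise=0.05)


@pytest.fixture(scope="session")
def bench_instances():
    """The five seeded benchmark instances used by the end-to-end checks."""
    out = {}
    for seed in range(1, 6):
        cfg = SynthConfig(seed=seed, **BENCH)
        out[seed] = simulate_instance(cfg)
    return out


@pytest.fixture
def sibling_dag():
    """Two sibling diseases under a single root."""
    return DiseaseOntology(
        terms={"root", "d1", "d2"},
        parents={"d1": {"root"}, "d2": {"root"}},
        w_e=0.5,
    )


@pytest.fixture
def diamond_dag():
    """Grandparent reachable from d by a 2-hop and a 3-hop path."""
    return DiseaseOntology(
        terms={"g", "p", "q", "r", "d"},
        parents={
            "d": {"p", "q"},
            "p": {"g"},       # d -> p -> g       (2 hops)
            "q": {"r"},
            "r": {"g"},       # d -> q -> r -> g  (3 hops)
        },
        w_e=0.5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
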