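"""Shared fixtures.

The full-pipeline fixtures are session-scoped because they are the expensive
study conditions (1000 uniform APS samples, 20 optimizer starts; the
seven-dimensional circuit runs at 1200 samples, the smallest size at which
the zero-noise DBSCAN radius resolves its sparse fourth mechanism family)
reused by the acceptance tests and several module tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from dorsalhorn.circuits import dynamic_circuit, simple_circuit, static_circuit
from dorsalhorn.constraints import presample_hierarchical
from dorsalhorn.pipeline import RunConfig, run_full_analysis

MASTER_SEED = 7


@pytest.fixture(scope="session")
def simple_spec():
    return simple_circuit()


@pytest.fixture(scope="session")
def static_spec():
    return static_circuit()


@pytest.fixture(scope="session")
def dynamic_spec():
    return dynamic_circuit()


@pytest.fixture(scope="session")
def simple_aps(simple_spec):
    """Hierarchical presample + normalization box for the simple circuit."""
    return presample_hierarchical(simple_spec, 1000, seed=11)


@pytest.fixture(scope="session")
def simple_pipeline():
    return run_full_analysis(RunConfig(circuit="simple", n_sample=1000,
                                       seed=MASTER_SEED))


@pytest.fixture(scope="session")
def static_pipeline():
    return run_full_analysis(RunConfig(circuit="static", n_sample=1000,
                                       seed=MASTER_SEED))


@pytest.fixture(scope="session")
def dynamic_pipeline():
    return run_full_analysis(RunConfig(circuit="dynamic", n_sample=1200,
                                       seed=MASTER_SEED))
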