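import numpy as np
import pytest
from hypothesis import settings

import fctbn
from fctbn import fixtures
from fctbn.design import compile_design

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    return fixtures.small_sim_spec(n_subjects=400, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """3-node reversible cohort, 400 subjects over 6 time units."""
    return fctbn.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_design(small_spec, small_cohort):
    return compile_design(small_spec.structure, small_cohort, standardize=True)


@pytest.fixture(scope="session")
def small_beta_tilde(small_spec, small_design):
    return fctbn.fit_unpenalized(small_spec.structure, design=small_design)


@pytest.fixture(scope="session")
def tiny_cohort():
    """20-subject cohort for IO and CLI round trips."""
    return fctbn.generate_cohort(fixtures.small_sim_spec(n_subjects=20, seed=3))


def edge_f1(found: set, truth: set) -> float:
    tp = len(found & truth)
    fp = len(found - truth)
    fn = len(truth - found)
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)
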