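import numpy as np
import pytest

from iuiselect import (
    Cohort,
    CycleRecord,
    ParameterSpec,
    load_reference_extremes,
    load_reference_parameters,
)
from iuiselect.synthetic import fixture_from_extremes


@pytest.fixture(scope="session")
def reference_specs():
    return load_reference_parameters()


@pytest.fixture(scope="session")
def reference_extremes():
    return load_reference_extremes()


@pytest.fixture(scope="session")
def reference_fixture_cohort(reference_extremes, reference_specs):
    """Cohort whose per-period group extremes equal the reference tables."""
    return fixture_from_extremes(
        reference_extremes, n_per_group=6, seed=20230430,
        parameters=reference_specs)


@pytest.fixture()
def two_param_specs():
    return [
        ParameterSpec("x", "female", "a.u.", direction_policy="both"),
        ParameterSpec("y", "ejaculate", "mL", direction_policy="upper"),
    ]


def make_cycle(cid, idx, period, values, pregnancy, multiple=None):
    return CycleRecord(
        couple_id=cid, cycle_index=idx, period=period, values=values,
        pregnancy=pregnancy, multiple_pregnancy=multiple)


@pytest.fixture()
def small_cohort(two_param_specs):
    cycles = [
        make_cycle("a", 1, "discovery", {"x": 1.0, "y": 2.0}, False),
        make_cycle("a", 2, "discovery", {"x": 1.5, "y": None}, True),
        make_cycle("b", 1, "discovery", {"x": 3.0, "y": 0.5}, False),
        make_cycle("c", 1, "validation", {"x": 2.0, "y": 1.0}, True, True),
        make_cycle("d", 1, "validation", {"x": 0.5, "y": 4.0}, False),
    ]
    return Cohort(cycles=cycles, parameters=two_param_specs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
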