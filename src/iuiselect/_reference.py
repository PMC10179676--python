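"""Bundled reference tables from the original clinical cohort.

Three text artifacts ship with the package:

* ``reference_parameters.csv`` — the parameter schema with the
  direction/source policy that reproduces the published threshold set;
* ``reference_extremes.json`` — per-period, per-outcome-group min/max for
  every parameter, usable with
  :func:`iuiselect.synthetic.fixture_from_extremes`;
* ``reference_thresholds.json`` — the eleven validated rules (seven male,
  four female) with their final published cutoffs.

``REFERENCE_SIGNIFICANT`` lists the six parameters that reached
significance in the published GEE fit.
"""

from __future__ import annotations

import json
from importlib import resources

from .cohort import ParameterSpec, read_parameters
from .thresholds import ThresholdRule

__all__ = [
    "REFERENCE_SIGNIFICANT",
    "load_reference_parameters",
    "load_reference_extremes",
    "load_reference_thresholds",
]

REFERENCE_SIGNIFICANT = (
    "male_age",
    "ejaculate_total_count",
    "swimup_alkaline_comet",
    "female_bmi",
    "infertility_duration",
    "lh",
)


def _data_path(name: str):
    return resources.files("iuiselect").joinpath("data", name)


def load_reference_parameters() -> list[ParameterSpec]:
    with resources.as_file(_data_path("reference_parameters.csv")) as p:
        return read_parameters(p)


def load_reference_extremes() -> dict:
    return json.loads(_data_path("reference_extremes.json").read_text())


def load_reference_thresholds() -> list[ThresholdRule]:
    payload = json.loads(_data_path("reference_thresholds.json").read_text())
    return [ThresholdRule(**item) for item in payload]
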