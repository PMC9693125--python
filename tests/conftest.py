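"""Shared fixtures: a default duct, small populations and field sets."""
from __future__ import annotations

import numpy as np
import pytest

from alveosim.calibration import default_substance_specs
from alveosim.geometry import GeometryConfig, build_duct
from alveosim.population import seed_cells
from alveosim.substances import FieldSet


@pytest.fixture(scope="session")
def duct():
    return build_duct(GeometryConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def pop(duct, rng):
    """Default full population (Table-1 counts on all 18 alveoli)."""
    return seed_cells(duct, rng=rng)


@pytest.fixture()
def fields():
    return FieldSet(default_substance_specs())


def make_fields(**overrides):
    """FieldSet with the default roster, selected specs replaced."""
    from dataclasses import replace

    specs = default_substance_specs()
    for name, kwargs in overrides.items():
        specs[name] = replace(specs[name], **kwargs)
    return FieldSet(specs)
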