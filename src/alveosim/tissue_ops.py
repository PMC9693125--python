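"""Standalone tissue-level operations.

These model boundary fluxes with the rest of the organ without explicit
agents: lymphocytes sourcing IL13 at each alveolus centre, fibroblast influx
from the interstitium gated by the healthy AEC2 count (prostaglandin E2
inhibition, a reverse Hill function with coefficient 1), monocyte influx
driven by locally sensed MCP1 (arrivals polarise immediately to M1), and the
surviving-alveolus count used as the functional-subunit survival readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DuctGeometry, voxel_indices
from .population import CellType, Population
from .substances import FieldSet

__all__ = [
    "InfluxSpec",
    "il13_source",
    "fibroblast_influx",
    "monocyte_influx",
    "count_surviving_alveoli",
]


@dataclass
class InfluxSpec:
    """Boundary-flux parameters (per-alveolus rates, per hour).

    ``fibro_hill_k`` is fixed to the initial healthy AEC2 count per alveolus,
    so the homeostatic influx modulation factor is exactly 1/2.  The default
    base rates close the homeostatic balance of the fibroblast and
    macrophage populations (see ``alveosim.calibration``).
    """

    fibro_base_rate: float = 0.0833333  # cells/h per alveolus
    fibro_hill_k: float = 69.0
    mono_base_rate: float = 0.0166667  # cells/h per alveolus
    mono_mcp1_gain: float = 3.0e4  # cells/h per (g/cm^3) of local MCP1
    il13_source_rate: float = 1.1111e-12  # g/h per alveolus centre

    def __post_init__(self):
        for v in (
            self.fibro_base_rate,
            self.fibro_hill_k,
            self.mono_base_rate,
            self.mono_mcp1_gain,
            self.il13_source_rate,
        ):
            if v < 0:
                raise ValueError("influx parameters must be non-negative")


def il13_source(fields: FieldSet, duct: DuctGeometry, spec: InfluxSpec, dt_h: float) -> None:
    """Deposit lymphocyte-derived IL13 at the voxel of each alveolus centre."""
    if spec.il13_source_rate == 0.0 or dt_h == 0.0:
        return
    idx = voxel_indices(duct.centers, fields.geometry)
    fields.deposit_rows("IL13", idx, np.full(duct.n_alveoli, spec.il13_source_rate * dt_h))


def fibroblast_influx_factor(n_aec2_healthy, k: float):
    """Reverse Hill modulation K/(K + n): 1 for a depleted alveolus, 1/2 at K."""
    return k / (k + np.asarray(n_aec2_healthy, dtype=float))


def fibroblast_influx(
    pop: Population,
    spec: InfluxSpec,
    rng: np.random.Generator,
    dt_h: float,
) -> int:
    """Poisson arrivals of fibroblasts on each interstitial shell.

    Expected arrivals per alveolus = base * K/(K + n_healthy_AEC2) * dt.
    Returns the total number of newcomers.
    """
    from .geometry import sample_on_sphere

    n_aec2 = pop.healthy_aec2_per_alveolus()
    lam = spec.fibro_base_rate * fibroblast_influx_factor(n_aec2, spec.fibro_hill_k) * dt_h
    arrivals = rng.poisson(lam)
    total = 0
    for alv, k in enumerate(arrivals):
        if k:
            pop.add(CellType.FIBROBLAST, alv, sample_on_sphere(int(k), rng))
            total += int(k)
    return total


def monocyte_influx(
    pop: Population,
    fields: FieldSet,
    spec: InfluxSpec,
    rng: np.random.Generator,
    dt_h: float,
    *,
    phagocytic_fraction: float = 1.0,
    phagocytic_index: int = 2,
) -> int:
    """Poisson arrivals of monocytes, instantiated directly as M1 macrophages.

    The arrival rate is base + gain * [MCP1], with MCP1 sampled at the
    alveolus-centre voxel; each arrival gets fresh phagocytic state and is
    flagged capable with probability ``phagocytic_fraction``.
    """
    from .geometry import sample_on_sphere

    idx = voxel_indices(pop.duct.centers, fields.geometry)
    mcp1 = fields.sample_rows("MCP1", idx)
    lam = (spec.mono_base_rate + spec.mono_mcp1_gain * mcp1) * dt_h
    arrivals = rng.poisson(lam)
    total = 0
    for alv, k in enumerate(arrivals):
        if k:
            rows = pop.add(
                CellType.M1,
                alv,
                sample_on_sphere(int(k), rng),
                phag_index=phagocytic_index,
            )
            pop.phag_capable[rows] = rng.random(int(k)) < phagocytic_fraction
            total += int(k)
    return total


def count_surviving_alveoli(pop: Population) -> int:
    """Alveoli with at least one *healthy* AEC2 (clonogenic survivors).

    Damaged and senescent AEC2 have lost clonogenic potential and do not
    count; a fully depleted alveolus can never recover.
    """
    return int(np.count_nonzero(pop.healthy_aec2_per_alveolus() > 0))
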