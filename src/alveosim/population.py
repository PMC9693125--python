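"""Cell-agent population container and neighbour queries.

Agents are points on spherical shells.  The population is stored
struct-of-arrays (numpy columns) so behaviour updates vectorise; individual
agents are addressed by row index, and every agent keeps a unique, never
reused integer id.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np
from scipy.spatial import cKDTree

from .geometry import DuctGeometry, GeometryConfig, Shell, sample_on_sphere

__all__ = ["CellType", "Phenotype", "Population", "seed_cells", "neighbors_within"]


class CellType(IntEnum):
    AEC1 = 0
    AEC2 = 1
    M1 = 2
    M2 = 3
    FIBROBLAST = 4
    MYOFIBROBLAST = 5


class Phenotype(IntEnum):
    """AEC2 phenotype; non-AEC2 agents carry HEALTHY throughout."""

    HEALTHY = 0
    DAMAGED = 1
    SENESCENT = 2


TYPE_SHELL = {
    CellType.AEC1: Shell.EPITHELIAL,
    CellType.AEC2: Shell.EPITHELIAL,
    CellType.M1: Shell.LUMINAL,
    CellType.M2: Shell.LUMINAL,
    CellType.FIBROBLAST: Shell.INTERSTITIAL,
    CellType.MYOFIBROBLAST: Shell.INTERSTITIAL,
}


def _type_radius(ctype: CellType, cfg: GeometryConfig) -> float:
    if ctype in (CellType.M1, CellType.M2):
        return cfg.macrophage_radius_um
    if ctype in (CellType.FIBROBLAST, CellType.MYOFIBROBLAST):
        return cfg.mesenchymal_cell_radius_um
    return cfg.epithelial_cell_radius_um


class Population:
    """Struct-of-arrays agent population bound to a duct geometry."""

    _COLUMNS = (
        "uid",
        "ctype",
        "alveolus",
        "unit",
        "shell_r",
        "radius",
        "phenotype",
        "tau",
        "damaged_timer",
        "eaten",
        "phag_index",
        "phag_capable",
    )

    def __init__(self, duct: DuctGeometry, capacity: int = 256):
        self.duct = duct
        self._centers = duct.centers  # cached (n_alveoli, 3)
        self._n = 0
        self._next_uid = 0
        self.uid = np.zeros(capacity, dtype=np.int64)
        self.ctype = np.zeros(capacity, dtype=np.int8)
        self.alveolus = np.zeros(capacity, dtype=np.int16)
        self.unit = np.zeros((capacity, 3), dtype=float)
        self.shell_r = np.zeros(capacity, dtype=float)
        self.radius = np.zeros(capacity, dtype=float)
        self.phenotype = np.zeros(capacity, dtype=np.int8)
        self.tau = np.zeros(capacity, dtype=float)  # hours above threshold
        self.damaged_timer = np.zeros(capacity, dtype=float)  # hours remaining
        self.eaten = np.zeros(capacity, dtype=np.int16)
        self.phag_index = np.zeros(capacity, dtype=np.int16)
        self.phag_capable = np.zeros(capacity, dtype=bool)

    # -- sizing ---------------------------------------------------------
    def __len__(self) -> int:
        return self._n

    @property
    def n(self) -> int:
        return self._n

    def _grow(self, extra: int) -> None:
        cap = len(self.uid)
        need = self._n + extra
        if need <= cap:
            return
        new_cap = max(2 * cap, need)
        for name in self._COLUMNS:
            arr = getattr(self, name)
            shape = (new_cap,) + arr.shape[1:]
            new = np.zeros(shape, dtype=arr.dtype)
            new[: self._n] = arr[: self._n]
            setattr(self, name, new)

    # -- mutation -------------------------------------------------------
    def add(
        self,
        ctype: CellType,
        alveolus_id,
        unit: np.ndarray,
        *,
        phenotype: Phenotype = Phenotype.HEALTHY,
        phag_index: int = 0,
        phag_capable: bool = False,
    ) -> np.ndarray:
        """Append agents of one type; ``unit`` is (k, 3) unit vectors.

        Returns the row indices of the new agents.
        """
        unit = np.atleast_2d(np.asarray(unit, dtype=float))
        k = unit.shape[0]
        alv = np.broadcast_to(np.asarray(alveolus_id, dtype=np.int16), (k,))
        self._grow(k)
        sl = slice(self._n, self._n + k)
        cfg = self.duct.config
        self.uid[sl] = np.arange(self._next_uid, self._next_uid + k)
        self._next_uid += k
        self.ctype[sl] = int(ctype)
        self.alveolus[sl] = alv
        self.unit[sl] = unit
        self.shell_r[sl] = cfg.shell_radius(TYPE_SHELL[CellType(ctype)])
        self.radius[sl] = _type_radius(CellType(ctype), cfg)
        self.phenotype[sl] = int(phenotype)
        self.tau[sl] = 0.0
        self.damaged_timer[sl] = 0.0
        self.eaten[sl] = 0
        self.phag_index[sl] = phag_index
        self.phag_capable[sl] = phag_capable
        self._n += k
        return np.arange(sl.start, sl.stop)

    def remove(self, rows: np.ndarray) -> None:
        """Delete agents by row index (compacting; row order of survivors kept)."""
        rows = np.asarray(rows, dtype=np.intp)
        if rows.size == 0:
            return
        keep = np.ones(self._n, dtype=bool)
        keep[rows] = False
        m = int(keep.sum())
        for name in self._COLUMNS:
            arr = getattr(self, name)
            arr[:m] = arr[: self._n][keep]
        self._n = m

    def change_type(self, rows: np.ndarray, new_type: CellType) -> None:
        """Differentiate: swap type, shell radius and agent radius in place."""
        rows = np.asarray(rows, dtype=np.intp)
        cfg = self.duct.config
        self.ctype[rows] = int(new_type)
        self.shell_r[rows] = cfg.shell_radius(TYPE_SHELL[new_type])
        self.radius[rows] = _type_radius(new_type, cfg)

    # -- views ----------------------------------------------------------
    def positions(self, rows=None) -> np.ndarray:
        """Cartesian positions (um): alveolus centre + shell_r * unit vector."""
        if rows is None:
            rows = slice(0, self._n)
        centers = self._centers[self.alveolus[rows]]
        return centers + self.shell_r[rows][:, None] * self.unit[rows]

    def mask(self, ctype: CellType, phenotype: Phenotype | None = None) -> np.ndarray:
        m = self.ctype[: self._n] == int(ctype)
        if phenotype is not None:
            m &= self.phenotype[: self._n] == int(phenotype)
        return m

    def rows(self, ctype: CellType, phenotype: Phenotype | None = None) -> np.ndarray:
        return np.flatnonzero(self.mask(ctype, phenotype))

    def counts(self) -> dict:
        """Population tallies keyed by readable names (AEC2 split by phenotype)."""
        out = {
            "AEC1": int(np.count_nonzero(self.mask(CellType.AEC1))),
            "AEC2_healthy": int(np.count_nonzero(self.mask(CellType.AEC2, Phenotype.HEALTHY))),
            "AEC2_damaged": int(np.count_nonzero(self.mask(CellType.AEC2, Phenotype.DAMAGED))),
            "AEC2_senescent": int(np.count_nonzero(self.mask(CellType.AEC2, Phenotype.SENESCENT))),
            "M1": int(np.count_nonzero(self.mask(CellType.M1))),
            "M2": int(np.count_nonzero(self.mask(CellType.M2))),
            "Fibroblast": int(np.count_nonzero(self.mask(CellType.FIBROBLAST))),
            "Myofibroblast": int(np.count_nonzero(self.mask(CellType.MYOFIBROBLAST))),
        }
        return out

    def healthy_aec2_per_alveolus(self) -> np.ndarray:
        """Healthy AEC2 tally per alveolus, shape (n_alveoli,)."""
        m = self.mask(CellType.AEC2, Phenotype.HEALTHY)
        return np.bincount(self.alveolus[: self._n][m], minlength=self.duct.n_alveoli)


DEFAULT_INITIAL_COUNTS = {
    CellType.AEC1: 41,
    CellType.AEC2: 69,
    CellType.M1: 6,
    CellType.M2: 6,
    CellType.FIBROBLAST: 24,
    CellType.MYOFIBROBLAST: 36,
}


def seed_cells(
    duct: DuctGeometry,
    initial_counts: dict | None = None,
    rng: np.random.Generator | None = None,
    *,
    phagocytic_fraction: float = 1.0,
    phagocytic_index: int = 2,
) -> Population:
    """Place the initial population uniformly on each alveolus's shells.

    ``initial_counts`` maps :class:`CellType` to the per-alveolus count.
    Macrophages are flagged phagocytosis-capable with probability
    ``phagocytic_fraction``.
    """
    counts = dict(DEFAULT_INITIAL_COUNTS)
    if initial_counts is not None:
        counts.update(initial_counts)
    for ct, c in counts.items():
        if c < 0:
            raise ValueError(f"negative initial count for {ct!r}")
    rng = rng or np.random.default_rng()
    total = sum(counts.values()) * duct.n_alveoli
    pop = Population(duct, capacity=max(256, int(total * 1.5)))
    for alv in duct.alveoli:
        for ctype, c in counts.items():
            if c == 0:
                continue
            units = sample_on_sphere(c, rng)
            if ctype in (CellType.M1, CellType.M2):
                capable = rng.random(c) < phagocytic_fraction
                pop.add(ctype, alv.id, units, phag_index=phagocytic_index,
                        phag_capable=False)
                # per-agent capability flags (add() broadcasts scalars only)
                pop.phag_capable[pop.n - c: pop.n] = capable
            else:
                pop.add(ctype, alv.id, units)
    return pop


def neighbors_within(
    pop: Population,
    row: int,
    distance: float,
    *,
    scope: str = "all",
    ctype: CellType | None = None,
    phenotype: Phenotype | None = None,
    brute_force: bool = False,
) -> np.ndarray:
    """Rows of agents within Euclidean ``distance`` of agent ``row``.

    ``scope`` is ``"all"`` or ``"same_alveolus"``.  Excludes the agent itself;
    result sorted by agent uid so the order is deterministic.  The KD-tree
    path must (and, by the test-suite contract, does) agree with the
    ``brute_force`` scan.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    pos = pop.positions()
    p0 = pos[row]
    if brute_force:
        d = np.linalg.norm(pos - p0, axis=1)
        hits = np.flatnonzero(d <= distance)
    else:
        tree = cKDTree(pos)
        hits = np.asarray(tree.query_ball_point(p0, distance), dtype=np.intp)
    hits = hits[hits != row]
    if scope == "same_alveolus":
        hits = hits[pop.alveolus[hits] == pop.alveolus[row]]
    elif scope != "all":
        raise ValueError("scope must be 'all' or 'same_alveolus'")
    if ctype is not None:
        hits = hits[pop.ctype[hits] == int(ctype)]
    if phenotype is not None:
        hits = hits[pop.phenotype[hits] == int(phenotype)]
    return hits[np.argsort(pop.uid[hits], kind="stable")]
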