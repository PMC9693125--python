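"""Cell behaviours: secretion, bystander damage, clearance, migration,
proliferation, differentiation and apoptosis.

All rates are expressed per hour of simulated time and converted to
per-evaluation probabilities with ``p = 1 - exp(-rate * dt)``, which keeps
trajectories statistically invariant when the biological step is refined.
Functions operate on a :class:`~alveosim.population.Population` in place and
are evaluated once per biological step by the engine, in the fixed category
order documented there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import voxel_indices
from .population import CellType, Phenotype, Population
from .substances import FieldSet

__all__ = [
    "RateTable",
    "BystanderParams",
    "ClearanceParams",
    "hazard_to_prob",
    "saturating",
    "secrete",
    "update_bystander",
    "mature_damaged",
    "phagocytose",
    "migrate_random",
    "migrate_informed",
    "proliferate",
    "differentiate",
    "apoptose",
    "enforce_min_separation",
    "EpithelialHood",
]

HOURS_PER_DAY = 24.0


def hazard_to_prob(rate_per_h: float | np.ndarray, dt_h: float) -> float | np.ndarray:
    """Per-evaluation probability of an event with the given hourly hazard."""
    return 1.0 - np.exp(-np.asarray(rate_per_h) * dt_h)


def saturating(conc, k_half):
    """Saturating modulation h(x) = x / (K + x); h(K) = 1/2, h(inf) -> 1."""
    c = np.asarray(conc, dtype=float)
    return c / (k_half + c)


@dataclass
class BystanderParams:
    """Senescence-induced senescence: neighbour threshold and escalation.

    A healthy AEC2 whose neighbourhood (within ``reach_um``, across alveoli)
    holds at least ``threshold`` senescent cells accumulates time-above-
    threshold tau (hours); otherwise tau decays.  The switch to the damaged
    state occurs with hazard ``k * tau`` per hour, i.e. per-evaluation
    probability 1 - exp(-k tau dt).
    """

    threshold: int = 2
    reach_um: float = 60.0  # two AEC2 diameters
    k: float = 1.2e-3  # 1/(h * tau-hour)
    damaged_min_h: float = 12.0
    damaged_max_h: float = 72.0

    def __post_init__(self):
        if self.threshold < 1 or self.reach_um <= 0 or self.k < 0:
            raise ValueError("invalid bystander parameters")


@dataclass
class ClearanceParams:
    phagocytic_fraction: float = 1.0
    phagocytic_index: int = 2
    contact_factor: float = 1.1  # contact reach = factor * (r_mac + r_target)


@dataclass
class RateTable:
    """Per-hour behaviour rates, migration speeds and secretion amounts.

    The defaults satisfy the homeostatic balance equations (see
    ``alveosim.calibration``): every population's gains equal its losses at
    the Table-1 cell numbers, so an unirradiated duct holds steady.
    Secretion amounts are grams per cell-hour; ``k_half`` holds the
    half-saturation concentrations of the modulation h(x) = x/(K+x),
    calibrated to the homeostatic concentration at the cells' own voxels.
    """

    # hazards (1/h)
    aec1_apoptosis: float = 1.0 / (120 * HOURS_PER_DAY)
    aec2_apoptosis: float = 1.0 / (120 * HOURS_PER_DAY)
    aec2_to_aec1: float = (41.0 / 69.0) / (120 * HOURS_PER_DAY)
    aec2_proliferation: float = (1.0 + 41.0 / 69.0) / (120 * HOURS_PER_DAY)
    mac_apoptosis: float = 1.0 / (30 * HOURS_PER_DAY)
    m1_to_m2: float = 1.5 / (30 * HOURS_PER_DAY)
    m2_to_m1_coeff: float = 1.0 / (30 * HOURS_PER_DAY)  # x h(TNFa); no base term
    f_apoptosis: float = 1.0 / (30 * HOURS_PER_DAY)
    f_prolif_base: float = 0.5 * (1.0 + 1.5) / (30 * HOURS_PER_DAY) / 2.0
    f_prolif_w: tuple = (1.0, 1.0, 1.0)  # TGFb_active, IL13, FGF2
    f_to_mf_base: float = 1.5 / (30 * HOURS_PER_DAY) / 2.0
    f_to_mf_w: tuple = (1.0, 1.0)  # PDGF, TGFb_active
    mf_apoptosis: float = 1.0 / (30 * HOURS_PER_DAY)
    # AEC1-count feedback on healthy AEC2 (fractions of the local reference)
    aec1_local_ref: float = 41.0 * 0.25  # spherical-cap fraction of one alveolus
    prolif_boost_below: float = 0.8
    apop_boost_above: float = 1.2
    # migration (um/h except the angular jitter in rad/h)
    mac_speed: float = 20.0
    mes_speed: float = 5.0
    epi_speed: float = 2.0
    damaged_jitter_rad: float = 0.05
    informed_eps_um: float = 1.0e-3
    # secretion amounts (g per cell per hour)
    q_m1_tnfa: float = 3.7037e-13
    q_m2_pdgf: float = 3.7037e-13
    q_m2_mmp: float = 6.2963e-13
    q_m2_timp: float = 5.5556e-13
    q_m2_il13: float = 1.8519e-13
    q_m2_tgfba: float = 3.7037e-13  # x h(IL13)
    q_f_tgfbi: float = 9.2593e-14
    q_f_ecm: float = 9.2593e-11  # x max(0, 1 - ECM/ecm_sat)
    q_mf_ecm: float = 6.1728e-11  # x h(TGFb_active)
    q_sen_tnfa: float = 3.7037e-13
    q_sen_mcp1: float = 3.2206e-13
    q_sen_fgf2: float = 3.2206e-13  # x h(TGFb_active)
    ecm_sat: float = 8.0e-3  # g/cm^3, fibroblast ECM secretion stops here
    # half-saturation concentrations for h(); populated by calibration
    k_half: dict = field(
        default_factory=lambda: {
            "TNFa": 1.0e-8,
            "TGFb_active": 1.0e-8,
            "IL13": 1.0e-8,
            "PDGF": 1.0e-8,
            "FGF2": 5.0e-8,
        }
    )

    def h(self, name: str, conc):
        return saturating(conc, self.k_half[name])


# ---------------------------------------------------------------------------
# secretion


def secrete(pop: Population, fields: FieldSet, rt: RateTable, dt_h: float) -> None:
    """Deposit substances into each secreting cell's voxel.

    Constant-rate species deposit q*dt; modulated species scale by h(local
    concentration) or, for fibroblast ECM, by the linear saturation factor
    max(0, 1 - ECM/ECM_sat).  Healthy/damaged AEC2 and AEC1 secrete nothing.
    """
    if dt_h == 0.0:
        return
    geo = fields.geometry

    def vox(mask):
        rows = np.flatnonzero(mask)
        return rows, voxel_indices(pop.positions(rows), geo)

    # M1: TNFa
    rows, idx = vox(pop.mask(CellType.M1))
    if rows.size:
        fields.deposit_rows("TNFa", idx, np.full(rows.size, rt.q_m1_tnfa * dt_h))
    # M2: PDGF, MMP, TIMP, IL13 constant; TGFb_active modulated by IL13
    rows, idx = vox(pop.mask(CellType.M2))
    if rows.size:
        for name, q in (
            ("PDGF", rt.q_m2_pdgf),
            ("MMP", rt.q_m2_mmp),
            ("TIMP", rt.q_m2_timp),
            ("IL13", rt.q_m2_il13),
        ):
            fields.deposit_rows(name, idx, np.full(rows.size, q * dt_h))
        il13 = fields.sample_rows("IL13", idx)
        fields.deposit_rows("TGFb_active", idx, rt.q_m2_tgfba * rt.h("IL13", il13) * dt_h)
    # Fibroblasts: latent TGFb constant; ECM with saturation shut-off
    rows, idx = vox(pop.mask(CellType.FIBROBLAST))
    if rows.size:
        fields.deposit_rows("TGFb_inactive", idx, np.full(rows.size, rt.q_f_tgfbi * dt_h))
        ecm = fields.sample_rows("ECM", idx)
        factor = np.clip(1.0 - ecm / rt.ecm_sat, 0.0, None)
        fields.deposit_rows("ECM", idx, rt.q_f_ecm * factor * dt_h)
    # Myofibroblasts: ECM driven by active TGFb
    rows, idx = vox(pop.mask(CellType.MYOFIBROBLAST))
    if rows.size:
        tgfb = fields.sample_rows("TGFb_active", idx)
        fields.deposit_rows("ECM", idx, rt.q_mf_ecm * rt.h("TGFb_active", tgfb) * dt_h)
    # Senescent AEC2 (SASP): TNFa + MCP1 constant, FGF2 driven by TGFb_active
    rows, idx = vox(pop.mask(CellType.AEC2, Phenotype.SENESCENT))
    if rows.size:
        fields.deposit_rows("TNFa", idx, np.full(rows.size, rt.q_sen_tnfa * dt_h))
        fields.deposit_rows("MCP1", idx, np.full(rows.size, rt.q_sen_mcp1 * dt_h))
        tgfb = fields.sample_rows("TGFb_active", idx)
        fields.deposit_rows("FGF2", idx, rt.q_sen_fgf2 * rt.h("TGFb_active", tgfb) * dt_h)


# ---------------------------------------------------------------------------
# bystander senescence and maturation


def senescent_neighbour_counts(pop: Population, rows: np.ndarray, reach_um: float) -> np.ndarray:
    """Number of senescent AEC2 within reach of each row (across alveoli)."""
    sen_rows = pop.rows(CellType.AEC2, Phenotype.SENESCENT)
    if sen_rows.size == 0 or rows.size == 0:
        return np.zeros(rows.size, dtype=int)
    tree = cKDTree(pop.positions(sen_rows))
    return np.asarray(
        tree.query_ball_point(pop.positions(rows), reach_um, return_length=True),
        dtype=int,
    )


def update_bystander(
    pop: Population,
    params: BystanderParams,
    rng: np.random.Generator,
    dt_h: float,
) -> int:
    """Advance tau for every healthy AEC2 and fire healthy->damaged switches.

    Returns the number of cells that switched this evaluation.
    """
    rows = pop.rows(CellType.AEC2, Phenotype.HEALTHY)
    if rows.size == 0:
        return 0
    counts = senescent_neighbour_counts(pop, rows, params.reach_um)
    above = counts >= params.threshold
    tau = pop.tau[rows]
    tau = np.where(above, tau + dt_h, np.maximum(0.0, tau - dt_h))
    pop.tau[rows] = tau
    p = 1.0 - np.exp(-params.k * tau * dt_h)
    hit = rows[rng.random(rows.size) < p]
    if hit.size:
        pop.phenotype[hit] = int(Phenotype.DAMAGED)
        pop.tau[hit] = 0.0
        pop.damaged_timer[hit] = rng.uniform(
            params.damaged_min_h, params.damaged_max_h, size=hit.size
        )
    return int(hit.size)


def draw_damaged_timer(params: BystanderParams, rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.uniform(params.damaged_min_h, params.damaged_max_h, size=n)


def mature_damaged(pop: Population, dt_h: float) -> int:
    """Tick down damaged-state timers; expire into the senescent phenotype."""
    rows = pop.rows(CellType.AEC2, Phenotype.DAMAGED)
    if rows.size == 0:
        return 0
    pop.damaged_timer[rows] -= dt_h
    done = rows[pop.damaged_timer[rows] <= 1e-9]
    pop.phenotype[done] = int(Phenotype.SENESCENT)
    pop.damaged_timer[done] = 0.0
    return int(done.size)


# ---------------------------------------------------------------------------
# phagocytosis


def phagocytose(
    pop: Population,
    params: ClearanceParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Macrophage clearance of senescent AEC2, same alveolus, contact range.

    Each capable macrophage below its phagocytic index may engulf at most one
    senescent cell per evaluation: the nearest unclaimed one in contact (ties
    broken by lower uid).  Returns the rows to remove; ``eaten`` counters are
    incremented here and macrophages that reach capacity stop moving.
    """
    sen_rows = pop.rows(CellType.AEC2, Phenotype.SENESCENT)
    if sen_rows.size == 0:
        return np.empty(0, dtype=np.intp)
    mac_mask = (pop.mask(CellType.M1) | pop.mask(CellType.M2))
    mac_mask &= pop.phag_capable[: pop.n]
    mac_mask &= pop.eaten[: pop.n] < pop.phag_index[: pop.n]
    mac_rows = np.flatnonzero(mac_mask)
    if mac_rows.size == 0:
        return np.empty(0, dtype=np.intp)

    eaten_rows: list = []
    sen_alv = pop.alveolus[sen_rows]
    mac_alv = pop.alveolus[mac_rows]
    for alv in np.unique(sen_alv):
        s = sen_rows[sen_alv == alv]
        m = mac_rows[mac_alv == alv]
        if m.size == 0:
            continue
        sp = pop.positions(s)
        mp = pop.positions(m)
        d = np.linalg.norm(mp[:, None, :] - sp[None, :, :], axis=2)
        reach = params.contact_factor * (pop.radius[m][:, None] + pop.radius[s][None, :])
        in_contact = d <= reach
        claimed = np.zeros(s.size, dtype=bool)
        for mi in rng.permutation(m.size):
            avail = in_contact[mi] & ~claimed
            if not avail.any():
                continue
            cand = np.flatnonzero(avail)
            order = np.lexsort((pop.uid[s[cand]], d[mi, cand]))
            pick = cand[order[0]]
            claimed[pick] = True
            eaten_rows.append(s[pick])
            pop.eaten[m[mi]] += 1
    return np.asarray(sorted(eaten_rows), dtype=np.intp)


# ---------------------------------------------------------------------------
# migration


def _tangent_basis(u: np.ndarray) -> tuple:
    """Orthonormal tangent-plane basis for each unit vector (rows of u)."""
    a = np.zeros_like(u)
    smallest = np.argmin(np.abs(u), axis=1)
    a[np.arange(len(u)), smallest] = 1.0
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(u, e1)
    return e1, e2


def geodesic_step(pop: Population, rows: np.ndarray, direction: np.ndarray, arc_um) -> None:
    """Rotate unit vectors along the great circle through tangent ``direction``."""
    if rows.size == 0:
        return
    u = pop.unit[rows]
    alpha = np.asarray(arc_um, dtype=float) / pop.shell_r[rows]
    t = direction / np.maximum(np.linalg.norm(direction, axis=1, keepdims=True), 1e-300)
    new = u * np.cos(alpha)[:, None] + t * np.sin(alpha)[:, None]
    new /= np.linalg.norm(new, axis=1, keepdims=True)
    pop.unit[rows] = new


def migrate_random(pop: Population, rt: RateTable, rng: np.random.Generator, dt_h: float) -> None:
    """Patrol/restock movement plus the slow jitter of injured AEC2.

    Macrophages below capacity and mesenchymal cells take a geodesic step of
    ``speed * dt`` in a uniformly random tangent direction.  Damaged and
    senescent AEC2 jitter their polar/azimuthal angles by uniform draws on
    [-delta, +delta] (zero included, i.e. chance stillness).  No move leaves
    the cell's alveolus or shell.
    """
    mac = (pop.mask(CellType.M1) | pop.mask(CellType.M2))
    mac &= pop.eaten[: pop.n] < pop.phag_index[: pop.n]
    mac_rows = np.flatnonzero(mac)
    mes_rows = np.flatnonzero(pop.mask(CellType.FIBROBLAST) | pop.mask(CellType.MYOFIBROBLAST))
    for rows, speed in ((mac_rows, rt.mac_speed), (mes_rows, rt.mes_speed)):
        if rows.size == 0 or speed == 0.0:
            continue
        u = pop.unit[rows]
        e1, e2 = _tangent_basis(u)
        psi = rng.uniform(0.0, 2.0 * np.pi, size=rows.size)
        t = e1 * np.cos(psi)[:, None] + e2 * np.sin(psi)[:, None]
        geodesic_step(pop, rows, t, speed * dt_h)

    inj = pop.mask(CellType.AEC2, Phenotype.DAMAGED) | pop.mask(CellType.AEC2, Phenotype.SENESCENT)
    rows = np.flatnonzero(inj)
    if rows.size:
        d = rt.damaged_jitter_rad * dt_h
        u = pop.unit[rows]
        theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0)) + rng.uniform(-d, d, rows.size)
        phi = np.arctan2(u[:, 1], u[:, 0]) + rng.uniform(-d, d, rows.size)
        theta = np.clip(theta, 1e-6, np.pi - 1e-6)
        pop.unit[rows] = np.column_stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )


def _informed_displacement(
    pos: np.ndarray, sensed: np.ndarray, reach: float, eps: float
) -> np.ndarray:
    """Per-agent vector away from the inverse-square-weighted neighbour COM.

    ``pos`` (n,3) acting agents, ``sensed`` (m,3) sensed agents (may overlap).
    Neighbours are sensed within ``reach``; weights are 1/(d/reach)^2.
    Rows with no neighbours or a symmetric neighbourhood get a zero vector.
    """
    if pos.size == 0 or sensed.size == 0:
        return np.zeros_like(pos)
    d = np.linalg.norm(pos[:, None, :] - sensed[None, :, :], axis=2)
    near = (d > 1e-9) & (d <= reach)
    w = np.where(near, (reach / np.maximum(d, 1e-9)) ** 2, 0.0)
    wsum = w.sum(axis=1)
    has = wsum > 0
    com = np.zeros_like(pos)
    com[has] = (w[has] @ sensed) / wsum[has, None]
    disp = np.where(has[:, None], pos - com, 0.0)
    disp[np.linalg.norm(disp, axis=1) < eps] = 0.0
    return disp


class EpithelialHood:
    """One per-step neighbourhood pass over the epithelial sheet.

    Computes, for every AEC1 and healthy AEC2, the away-from-centre-of-mass
    displacement used by informed migration (AEC1 sense AEC1, healthy AEC2
    sense all AEC1/AEC2) and the local AEC1 tally used by the proliferation
    and apoptosis feedback — all within one alveolar radius, same alveolus.
    Uses the compiled kernel when numba is available; otherwise falls back
    to an equivalent numpy tensor path, which the test
    suite holds equal to the kernel.
    """

    def __init__(self, pop: Population, use_numba: bool | None = None):
        from ._kernels import HAVE_NUMBA, epithelial_hood_kernel

        self.pop = pop
        n_alv = pop.duct.n_alveoli
        epi = np.flatnonzero(pop.mask(CellType.AEC1) | pop.mask(CellType.AEC2))
        alv = pop.alveolus[epi]
        order = np.argsort(alv, kind="stable")
        self.rows = epi[order]
        alv = alv[order]
        counts = np.bincount(alv, minlength=n_alv)
        self.start = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        self.is_aec1 = pop.ctype[self.rows] == int(CellType.AEC1)
        self.is_h2 = (pop.ctype[self.rows] == int(CellType.AEC2)) & (
            pop.phenotype[self.rows] == int(Phenotype.HEALTHY)
        )
        self.index_of = np.full(pop.n, -1, dtype=np.intp)
        self.index_of[self.rows] = np.arange(self.rows.size)
        reach = pop.duct.alveolus_radius
        pos = pop.positions(self.rows)
        if use_numba is None:
            use_numba = HAVE_NUMBA
        if use_numba:
            self.disp, self.aec1_count = epithelial_hood_kernel(
                pos, self.start, self.is_aec1, self.is_h2, reach, 1.0e-3
            )
        else:
            self.disp, self.aec1_count = self._numpy_pass(pos, reach, 1.0e-3)

    def _numpy_pass(self, pos, reach, eps):
        n = pos.shape[0]
        disp = np.zeros((n, 3))
        cnt = np.zeros(n, dtype=np.int64)
        r2 = reach * reach
        for a in range(self.start.size - 1):
            s, e = int(self.start[a]), int(self.start[a + 1])
            if e - s == 0:
                continue
            p = pos[s:e]
            d = p[:, None, :] - p[None, :, :]
            d2 = np.einsum("ijk,ijk->ij", d, d)
            np.fill_diagonal(d2, np.inf)
            near = d2 <= r2
            a1 = self.is_aec1[s:e]
            cnt[s:e] = (near & a1[None, :]).sum(axis=1)
            w = np.where(near, r2 / np.maximum(d2, 1e-6), 0.0)
            for actor, cols in ((self.is_aec1[s:e], a1), (self.is_h2[s:e], None)):
                ww = w if cols is None else w * cols[None, :]
                wsum = ww.sum(axis=1)
                act = actor & (wsum > 0)
                if not act.any():
                    continue
                com = (ww[act] @ p) / wsum[act][:, None]
                dv = p[act] - com
                dv[np.einsum("ij,ij->i", dv, dv) < eps * eps] = 0.0
                disp[np.flatnonzero(act) + s] = dv
        return disp, cnt


def migrate_informed(
    pop: Population, rt: RateTable, dt_h: float, hood: EpithelialHood | None = None
) -> None:
    """Epithelial spreading away from crowded regions.

    AEC1 sense AEC1; healthy AEC2 sense AEC1 and AEC2 (any phenotype), in the
    same alveolus within one alveolar radius.  The cell moves opposite the
    tangential component of the inverse-square-weighted neighbour centre of
    mass at constant speed (simultaneous update: everyone senses the same
    snapshot of the sheet).
    """
    if rt.epi_speed == 0.0 or dt_h == 0.0:
        return
    if hood is None:
        hood = EpithelialHood(pop)
    moving = np.flatnonzero(np.einsum("ij,ij->i", hood.disp, hood.disp) > 0)
    if moving.size:
        _informed_move(pop, hood.rows[moving], hood.disp[moving], rt.epi_speed * dt_h)


def _informed_move(pop: Population, rows: np.ndarray, disp: np.ndarray, arc_um: float) -> None:
    u = pop.unit[rows]
    tang = disp - (np.sum(disp * u, axis=1, keepdims=True)) * u
    norm = np.linalg.norm(tang, axis=1)
    moving = norm > 1e-12
    if moving.any():
        geodesic_step(pop, rows[moving], tang[moving], arc_um)


def enforce_min_separation(pop: Population, rng: np.random.Generator, passes: int = 3) -> None:
    """Nudge same-shell overlapping agents apart (min gap 0.5 x summed radii).

    Each pass resolves all violating same-(alveolus, shell) pairs at once:
    every agent accumulates half the missing separation away from each
    too-close partner (plus a small margin), then takes one geodesic step of
    the summed tangent displacement.
    """
    from ._kernels import separation_push_kernel

    if pop.n < 2:
        return
    key = pop.alveolus[: pop.n].astype(np.int64) * 8 + np.digitize(
        pop.shell_r[: pop.n], np.unique(pop.shell_r[: pop.n])
    )
    order = np.argsort(key, kind="stable")
    bounds = np.flatnonzero(np.diff(key[order])) + 1
    start = np.concatenate([[0], bounds, [pop.n]]).astype(np.int64)
    radius = pop.radius[order]
    for _ in range(passes):
        pos = pop.positions(order)
        push, hit = separation_push_kernel(pos, radius, start)
        if not hit:
            break
        arc = np.linalg.norm(push, axis=1)
        act = np.flatnonzero(arc > 1e-12)
        geodesic_step(pop, order[act], push[act], arc[act])


# ---------------------------------------------------------------------------
# neighbourhood tallies for the epithelial feedback loops


def local_aec1_counts(
    pop: Population, rows: np.ndarray, hood: EpithelialHood | None = None
) -> np.ndarray:
    """AEC1 within one alveolar radius, same alveolus, for each given row."""
    rows = np.asarray(rows, dtype=np.intp)
    if rows.size == 0:
        return np.zeros(0, dtype=int)
    if hood is None:
        hood = EpithelialHood(pop)
    return hood.aec1_count[hood.index_of[rows]]


# ---------------------------------------------------------------------------
# proliferation


def proliferate(
    pop: Population,
    fields: FieldSet,
    rt: RateTable,
    rng: np.random.Generator,
    dt_h: float,
    hood: EpithelialHood | None = None,
) -> int:
    """Symmetric division of healthy AEC2 and fibroblasts.

    AEC2 double their hazard when the local AEC1 count drops below 80% of the
    homeostatic reference (hyperplastic repopulation); fibroblast hazard is
    boosted by active TGF-beta, IL13 and FGF2.  Daughters appear one agent
    diameter away in a random tangent direction, on the parent's shell.
    Returns the number of daughters created.
    """
    born = 0
    rows = pop.rows(CellType.AEC2, Phenotype.HEALTHY)
    if hood is not None:
        rows = rows[hood.index_of[rows] >= 0]  # daughters act next evaluation
    if rows.size:
        n1 = local_aec1_counts(pop, rows, hood)
        hazard = np.where(
            n1 < rt.prolif_boost_below * rt.aec1_local_ref,
            2.0 * rt.aec2_proliferation,
            rt.aec2_proliferation,
        )
        div = rows[rng.random(rows.size) < hazard_to_prob(hazard, dt_h)]
        born += _spawn_daughters(pop, div, CellType.AEC2, rng)
    f_rows = pop.rows(CellType.FIBROBLAST)
    if f_rows.size:
        idx = voxel_indices(pop.positions(f_rows), fields.geometry)
        w1, w2, w3 = rt.f_prolif_w
        hazard = rt.f_prolif_base * (
            1.0
            + w1 * rt.h("TGFb_active", fields.sample_rows("TGFb_active", idx))
            + w2 * rt.h("IL13", fields.sample_rows("IL13", idx))
            + w3 * rt.h("FGF2", fields.sample_rows("FGF2", idx))
        )
        div = f_rows[rng.random(f_rows.size) < hazard_to_prob(hazard, dt_h)]
        born += _spawn_daughters(pop, div, CellType.FIBROBLAST, rng)
    return born


def fibroblast_prolif_hazard(rt: RateTable, tgfb: float, il13: float, fgf2: float) -> float:
    """Scalar fibroblast division hazard for given local concentrations."""
    w1, w2, w3 = rt.f_prolif_w
    return rt.f_prolif_base * (
        1.0
        + w1 * rt.h("TGFb_active", tgfb)
        + w2 * rt.h("IL13", il13)
        + w3 * rt.h("FGF2", fgf2)
    )


def _spawn_daughters(
    pop: Population, parents: np.ndarray, ctype: CellType, rng: np.random.Generator
) -> int:
    if parents.size == 0:
        return 0
    u = pop.unit[parents].copy()
    alv = pop.alveolus[parents].copy()
    shell_r = pop.shell_r[parents].copy()
    radius = pop.radius[parents].copy()
    e1, e2 = _tangent_basis(u)
    psi = rng.uniform(0.0, 2.0 * np.pi, size=parents.size)
    t = e1 * np.cos(psi)[:, None] + e2 * np.sin(psi)[:, None]
    alpha = (2.0 * radius) / shell_r  # one agent diameter along the surface
    new_u = u * np.cos(alpha)[:, None] + t * np.sin(alpha)[:, None]
    new_u /= np.linalg.norm(new_u, axis=1, keepdims=True)
    for k in range(parents.size):
        pop.add(ctype, int(alv[k]), new_u[k])
    return int(parents.size)


# ---------------------------------------------------------------------------
# differentiation


def differentiate(
    pop: Population,
    fields: FieldSet,
    rt: RateTable,
    rng: np.random.Generator,
    dt_h: float,
) -> dict:
    """Type switches: M1->M2, M2->M1 (TNFa-driven), F->MF, healthy AEC2->AEC1.

    Returns a tally of transitions per channel.
    """
    tally = {"m1_to_m2": 0, "m2_to_m1": 0, "f_to_mf": 0, "aec2_to_aec1": 0}
    geo = fields.geometry

    m1 = pop.rows(CellType.M1)
    hit_m1 = m1[rng.random(m1.size) < hazard_to_prob(rt.m1_to_m2, dt_h)]
    m2 = pop.rows(CellType.M2)
    if m2.size:
        tnfa = fields.sample_rows("TNFa", voxel_indices(pop.positions(m2), geo))
        hazard = rt.m2_to_m1_coeff * rt.h("TNFa", tnfa)
        hit_m2 = m2[rng.random(m2.size) < hazard_to_prob(hazard, dt_h)]
    else:
        hit_m2 = m2
    f = pop.rows(CellType.FIBROBLAST)
    if f.size:
        idx = voxel_indices(pop.positions(f), geo)
        w4, w5 = rt.f_to_mf_w
        hazard = rt.f_to_mf_base * (
            1.0
            + w4 * rt.h("PDGF", fields.sample_rows("PDGF", idx))
            + w5 * rt.h("TGFb_active", fields.sample_rows("TGFb_active", idx))
        )
        hit_f = f[rng.random(f.size) < hazard_to_prob(hazard, dt_h)]
    else:
        hit_f = f
    a2 = pop.rows(CellType.AEC2, Phenotype.HEALTHY)
    hit_a2 = a2[rng.random(a2.size) < hazard_to_prob(rt.aec2_to_aec1, dt_h)]

    pop.change_type(hit_m1, CellType.M2)
    pop.change_type(hit_m2, CellType.M1)
    pop.change_type(hit_f, CellType.MYOFIBROBLAST)
    pop.change_type(hit_a2, CellType.AEC1)
    pop.tau[hit_a2] = 0.0
    tally["m1_to_m2"] = int(hit_m1.size)
    tally["m2_to_m1"] = int(hit_m2.size)
    tally["f_to_mf"] = int(hit_f.size)
    tally["aec2_to_aec1"] = int(hit_a2.size)
    return tally


# ---------------------------------------------------------------------------
# apoptosis


def apoptose(
    pop: Population,
    rt: RateTable,
    rng: np.random.Generator,
    dt_h: float,
    hood: EpithelialHood | None = None,
) -> np.ndarray:
    """Rows to remove this evaluation.

    AEC1, macrophages and mesenchymal cells die at constant hazard; healthy
    AEC2 double their hazard when crowded by AEC1 (local count above 120% of
    the homeostatic reference).  Damaged and senescent AEC2 never apoptose.
    """
    doomed = []
    for ctype, rate in (
        (CellType.AEC1, rt.aec1_apoptosis),
        (CellType.M1, rt.mac_apoptosis),
        (CellType.M2, rt.mac_apoptosis),
        (CellType.FIBROBLAST, rt.f_apoptosis),
        (CellType.MYOFIBROBLAST, rt.mf_apoptosis),
    ):
        rows = pop.rows(ctype)
        if rows.size:
            doomed.append(rows[rng.random(rows.size) < hazard_to_prob(rate, dt_h)])
    rows = pop.rows(CellType.AEC2, Phenotype.HEALTHY)
    if hood is not None:
        rows = rows[rows < hood.index_of.size]  # daughters act next evaluation
        rows = rows[hood.index_of[rows] >= 0]
    if rows.size:
        n1 = local_aec1_counts(pop, rows, hood)
        hazard = np.where(
            n1 > rt.apop_boost_above * rt.aec1_local_ref,
            2.0 * rt.aec2_apoptosis,
            rt.aec2_apoptosis,
        )
        doomed.append(rows[rng.random(rows.size) < hazard_to_prob(hazard, dt_h)])
    if not doomed:
        return np.empty(0, dtype=np.intp)
    return np.unique(np.concatenate(doomed)).astype(np.intp)
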