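"""Homeostatic calibration of rates, influx and substance kinetics.

The duct must hold its Table-of-initial-counts populations and substance
levels steady indefinitely when unirradiated.  Rather than trial and error,
the defaults are derived from balance equations at the initial counts
(per alveolus: 41 AEC1, 69 healthy AEC2, 6 M1, 6 M2, 24 F, 36 MF):

* AEC1:  69 * r(AEC2->AEC1)            = 41 * r(apop, AEC1)
* AEC2:  r(prolif, AEC2)               = r(apop, AEC2) + r(AEC2->AEC1)
* M1:    mono influx + 6 * r(M2->M1)*  = 6 * (r(apop, M) + r(M1->M2))
* M2:    6 * r(M1->M2)                 = 6 * (r(apop, M) + r(M2->M1)*)
* F:     influx/2 + 24 * r(prolif,F)*  = 24 * (r(apop, F) + r(F->MF)*)
* MF:    24 * r(F->MF)*                = 36 * (r(apop, MF))

Starred rates are the *effective* homeostatic hazards: every concentration
modulation h(x) = x/(K+x) evaluates to 1/2 because each K is calibrated to
that substance's homeostatic concentration at the cells' own voxels, and the
fibroblast ECM saturation factor 1 - ECM/ECM_sat is 1/2 because ECM_sat is
set to twice the homeostatic ECM level.  Default lifespans: AEC1 and AEC2
120 d, macrophages 30 d, fibroblasts and myofibroblasts 60 d.

Substance secretion amounts are back-solved from declared homeostatic
concentration targets (cytokines ~1e-8 g/cm^3, ECM ~4e-3 g/cm^3 in the
central voxels) given the decay/binding network; ``equilibrate_fields`` then
relaxes the spatial fields to their true steady state with the cells frozen
as sources, and ``calibrate_field_response`` pins the K constants to the
measured levels.
"""

from __future__ import annotations

import numpy as np

from .agents import RateTable, secrete
from .population import Population
from .substances import BindingTerm, FieldSet, SubstanceSpec
from .tissue_ops import InfluxSpec, il13_source

__all__ = [
    "default_substance_specs",
    "default_rate_table",
    "default_influx_spec",
    "equilibrate_fields",
    "calibrate_field_response",
]

PER_H = 1.0 / 3600.0  # convert per-hour rates to per-second

#: declared homeostatic whole-space mean targets, g/cm^3
TARGET_MEANS = {
    "TNFa": 1.0e-8,
    "IL13": 1.0e-8,
    "PDGF": 1.0e-8,
    "TGFb_active": 1.0e-8,
    "TGFb_inactive": 2.5e-8,
    "MMP": 1.0e-8,
    "TIMP": 1.0e-8,
}

#: cytokine diffusion coefficient, um^2/s (1e-6 cm^2/s scale); CFL-stable
#: at dt = 1 s on a 500 um grid by a wide margin.
DIFF_UM2_S = 100.0
DECAY_FAST = 0.5 * PER_H  # cytokines, half-life ~1.4 h
TGFBI_DECAY = 0.1 * PER_H
TGFB_ACTIVATION = 0.1 * PER_H  # first-order latent -> active conversion


def default_substance_specs() -> dict:
    """The ten-substance roster with its default kinetic network.

    MMP degrades ECM (both consumed, strongly asymmetric coefficients: one
    protease clears many times its mass of matrix), TIMP neutralises MMP
    (both consumed), latent TGF-beta activates at a constant first-order
    rate.  ECM neither diffuses nor decays.
    """
    k_ecm_loss = 3.3333e5 * PER_H  # ECM loss per (g/cm^3 of MMP): 0.01/h at MMP ~3e-8
    k_mmp_by_ecm = 25.0 * PER_H  # MMP loss per (g/cm^3 of ECM): 0.1/h at ECM 4e-3
    k_mmp_timp = 2.5e7 * PER_H  # 0.25/h at the 1e-8 homeostatic partner level
    specs = {}
    for name in ("MCP1", "TNFa", "FGF2", "PDGF", "IL13"):
        specs[name] = SubstanceSpec(name, DIFF_UM2_S, DECAY_FAST, init_conc=0.0)
    specs["TGFb_active"] = SubstanceSpec("TGFb_active", DIFF_UM2_S, DECAY_FAST)
    specs["TGFb_inactive"] = SubstanceSpec(
        "TGFb_inactive",
        DIFF_UM2_S,
        TGFBI_DECAY,
        bindings=(BindingTerm(None, TGFB_ACTIVATION, "converted_to:TGFb_active"),),
    )
    specs["MMP"] = SubstanceSpec(
        "MMP",
        DIFF_UM2_S,
        DECAY_FAST,
        bindings=(
            BindingTerm("TIMP", k_mmp_timp, "consumed"),
            BindingTerm("ECM", k_mmp_by_ecm, "consumed"),
        ),
    )
    specs["TIMP"] = SubstanceSpec(
        "TIMP",
        DIFF_UM2_S,
        DECAY_FAST,
        bindings=(BindingTerm("MMP", k_mmp_timp, "consumed"),),
    )
    specs["ECM"] = SubstanceSpec(
        "ECM",
        0.0,
        0.0,
        bindings=(BindingTerm("MMP", k_ecm_loss, "consumed"),),
    )
    # uniform initial guesses at the target means; the burn-in relaxation
    # replaces these with the true spatial steady state
    out = {}
    for name, spec in specs.items():
        init = TARGET_MEANS.get(name, 0.0)
        out[name] = SubstanceSpec(
            spec.name, spec.diff_coeff_um2_s, spec.decay_per_s, init, spec.bindings
        )
    return out


def default_rate_table() -> RateTable:
    """RateTable defaults already satisfy the balance equations; see class."""
    return RateTable()


def default_influx_spec() -> InfluxSpec:
    return InfluxSpec()


def equilibrate_fields(
    fields: FieldSet,
    pop: Population,
    rt: RateTable,
    influx: InfluxSpec,
    hours: float = 400.0,
    dt_s: float = 360.0,
) -> None:
    """Relax all substance fields with the cells frozen as sources.

    Runs secretion + boundary IL13 sourcing + diffusion/decay/binding only,
    no cell dynamics, so recorded runs start at (and stay near) the spatial
    steady state instead of drifting from an analytic uniform guess.
    """
    from .geometry import voxel_indices
    from .population import CellType, Phenotype

    dt_s = min(dt_s, fields.max_stable_dt())
    n = int(round(hours * 3600.0 / dt_s))
    dt_h = dt_s / 3600.0
    any_senescent = bool(np.count_nonzero(pop.mask(CellType.AEC2, Phenotype.SENESCENT)))
    if any_senescent:
        # rare path (post-injury equilibration): use the generic secretion
        for _ in range(n):
            secrete(pop, fields, rt, dt_h)
            il13_source(fields, pop.duct, influx, dt_h)
            fields.step_diffusion(dt_s)
        return

    # frozen cells: precompute the constant-rate source grid once
    v = fields.voxel_volume_cm3
    const = np.zeros_like(fields.data)  # conc per hour

    def grid(name):
        return const[fields._index[name]]

    def add_const(name, rows_mask, q_per_h):
        rows = np.flatnonzero(rows_mask)
        if rows.size:
            idx = voxel_indices(pop.positions(rows), fields.geometry)
            np.add.at(grid(name), (idx[:, 0], idx[:, 1], idx[:, 2]), q_per_h / v)

    add_const("TNFa", pop.mask(CellType.M1), rt.q_m1_tnfa)
    m2 = pop.mask(CellType.M2)
    for name, q in (("PDGF", rt.q_m2_pdgf), ("MMP", rt.q_m2_mmp),
                    ("TIMP", rt.q_m2_timp), ("IL13", rt.q_m2_il13)):
        add_const(name, m2, q)
    add_const("TGFb_inactive", pop.mask(CellType.FIBROBLAST), rt.q_f_tgfbi)
    centre_idx = voxel_indices(pop.duct.centers, fields.geometry)
    np.add.at(grid("IL13"), (centre_idx[:, 0], centre_idx[:, 1], centre_idx[:, 2]),
              influx.il13_source_rate / v)
    m2_idx = voxel_indices(pop.positions(np.flatnonzero(m2)), fields.geometry)
    f_idx = voxel_indices(
        pop.positions(np.flatnonzero(pop.mask(CellType.FIBROBLAST))), fields.geometry
    )
    mf_idx = voxel_indices(
        pop.positions(np.flatnonzero(pop.mask(CellType.MYOFIBROBLAST))), fields.geometry
    )
    for _ in range(n):
        fields.data += const * dt_h
        # concentration-modulated secretion re-evaluated each step
        il13 = fields.sample_rows("IL13", m2_idx)
        fields.deposit_rows("TGFb_active", m2_idx, rt.q_m2_tgfba * rt.h("IL13", il13) * dt_h)
        ecm = fields.sample_rows("ECM", f_idx)
        fields.deposit_rows(
            "ECM", f_idx, rt.q_f_ecm * np.clip(1.0 - ecm / rt.ecm_sat, 0.0, None) * dt_h
        )
        tgfb = fields.sample_rows("TGFb_active", mf_idx)
        fields.deposit_rows("ECM", mf_idx, rt.q_mf_ecm * rt.h("TGFb_active", tgfb) * dt_h)
        fields.step_diffusion(dt_s)


def central_means(fields: FieldSet, pop: Population) -> dict:
    """Mean concentration over the voxels the cells actually occupy."""
    from .geometry import voxel_indices

    idx = voxel_indices(pop.positions(), fields.geometry)
    uniq = np.unique(idx, axis=0)
    return {
        name: float(fields.fields[name][uniq[:, 0], uniq[:, 1], uniq[:, 2]].mean())
        for name in fields.fields
    }


def calibrate_field_response(
    fields: FieldSet,
    pop: Population,
    rt: RateTable,
    influx: InfluxSpec,
    rounds: int = 2,
    hours_per_round: float = 300.0,
) -> None:
    """Pin the h() half-saturations and ECM saturation to measured levels.

    Alternates a field relaxation with resetting each K (and ECM_sat = 2x
    the homeostatic ECM) to the concentrations at the cells' voxels, so that
    every modulation factor is exactly 1/2 in homeostasis — the value the
    population balance equations assume.  FGF2 has no homeostatic level (it
    is senescence-only) and keeps its configured K.
    """
    for _ in range(rounds):
        equilibrate_fields(fields, pop, rt, influx, hours=hours_per_round)
        means = central_means(fields, pop)
        for name in ("TNFa", "TGFb_active", "IL13", "PDGF"):
            if means[name] > 0:
                rt.k_half[name] = means[name]
        if means["ECM"] > 0:
            rt.ecm_sat = 2.0 * means["ECM"]
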