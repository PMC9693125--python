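# Methods

This document describes the model implemented by `alveosim`: geometry, cell
agents, the substance field, irradiation, the simulation engine, the analysis
layer, the calibration that produced the default parameters, and the known
limitations of the resulting model.

## 1. Geometry

The simulated tissue is a 2000 µm cube containing an alveolar duct of 18
spherical alveoli (radius `r = 125` µm): three axial layers of six alveoli,
each layer a ring tangent to its neighbours, layers tangent to each other,
centred in the cube. Each alveolus carries two concentric shells on which
agents live:

* **epithelial** shell (radius `r`): AEC1 and AEC2;
* **interstitial** shell (radius `1.08 r`): macrophages, fibroblasts,
  myofibroblasts.

Positions are points on the shell; on-shell motion is geodesic. The cube is
voxelised 4×4×4 (voxel side 500 µm) for the substance field; an agent sources
into / samples from the voxel containing its position (half-open voxel
boundaries, upper faces clipped inward).

## 2. Cell populations

Per alveolus at homeostasis: 41 AEC1, 69 healthy AEC2, 6 M1 and 6 M2
macrophages, 24 fibroblasts, 36 myofibroblasts (total 3 276 agents in the
duct). AEC2 can be *healthy*, *damaged* (irradiation- or bystander-hit,
counting down a maturation timer) or *senescent*. The population is a
structure-of-arrays with stable unique ids; neighbour queries use a k-d tree
and are contract-tested against brute force.

## 3. Substance field

Ten substances diffuse and decay on the voxel grid with zero-flux
boundaries: MCP-1, TNF-α, FGF-2, TGF-β (inactive and active), PDGF, IL-13,
MMP, TIMP, and ECM (ECM does not diffuse). The solver is explicit
FTCS (forward-time central-space); the step is capped at the stability limit
`dt ≤ dx²/6D` and mass is conserved to 1 part in 10⁹ over 10⁴ steps.
Reaction terms — first-order decay, MMP-mediated ECM degradation
(pair-binding loss) and TGF-β activation (conversion) — are evaluated on
pre-step values so operator order cannot bias the result; negative
concentrations are clamped and counted.

Secretion network (per-hour point sources at agent positions):

| source | secretes |
| --- | --- |
| M1 | TNF-α |
| M2 | PDGF, MMP, IL-13, active TGF-β (gated by IL-13) |
| senescent AEC2 | TNF-α, MCP-1, FGF-2 (gated by active TGF-β) |
| fibroblast | inactive TGF-β; ECM (shut off as ECM approaches saturation) |
| myofibroblast | ECM (gated by active TGF-β, Michaelis form `c/(K+c)`) |

MMP additionally loses mass to TIMP inhibition and to the ECM it degrades
(symmetric pair-binding terms).

All gates are saturating Hill-type factors `h(c) = c/(K_half + c)` with
`K_half` pinned during calibration to the homeostatic mean of the respective
substance, so every gate sits at ½ at baseline.

## 4. Irradiation

Single-fraction linear–quadratic survival `S(D) = exp(−αD − βD²)`, with
(α, β) solved exactly from two anchors: 95 % AEC2 survival at 0.6 Gy and 1 %
at 17.6 Gy, giving α = 0.07927 Gy⁻¹, β = 0.010363 Gy⁻² (α/β = 7.65 Gy).
Only healthy AEC2 are targets. Per alveolus the number of hit cells is
`min(Poisson(N·(1−S)), N)`; a fraction `senescent_fraction` of the hit cells
becomes *damaged* with a uniform 12–72 h maturation timer, the rest apoptose
immediately. Note the truncation at the available `N = 69` cells is not
cosmetic at high dose: at 17.6 Gy the exact mean of `min(X, 69)` with
`X ~ Poisson(68.31)` is 65.35, so the realised mean surviving fraction is
≈ 5.3 %, above the 1 % cell-survival anchor (see Limitations).

## 5. Senescence, bystander effect, clearance

Damaged AEC2 mature into senescent AEC2 when their timer expires. A healthy
AEC2 with at least 2 senescent neighbours within 60 µm accumulates exposure
time τ (h); per hourly evaluation it becomes damaged with probability
`p = 1 − exp(−k·τ·Δt)`, `k = 1.2·10⁻³ h⁻²`; τ ratchets down when the
neighbour count falls below threshold. Senescent cells are removed by
phagocytosis: each M1/M2 macrophage (phagocytic fraction 1.0) engulfs at
most one contacted senescent cell per evaluation, choosing the nearest
(ties by id), up to a lifetime capacity of 2 (the *phagocytic index*).
Inflammation recruits reinforcements: senescent-derived MCP-1 drives
Poisson monocyte influx (arrivals enter as M1 with fresh phagocytic
capacity), and a baseline fibroblast influx (0.0833 h⁻¹, crowding-limited)
maintains the mesenchymal pool.

The phagocytic index of 2 is the dose discriminator of the model: the
resident macrophage pool can engulf ~24 senescent cells per alveolus, which
promptly clears the small senescent burden of doses ≤ 4 Gy but saturates at
fibrosing doses, where clearance has to wait for MCP-1-recruited monocytes —
this is what makes inflammation duration, and hence ECM deposition, strongly
dose-dependent.

## 6. Repair and fibrosis

AEC2 proliferate (and can differentiate into AEC1) with a rate doubled when
the local AEC1 count falls below 80 % of its homeostatic reference; AEC2
apoptosis doubles above 120 % crowding. Fibroblast proliferation is an
increasing saturating function of local active TGF-β, IL-13 and FGF-2, and
fibroblast→myofibroblast differentiation of PDGF and active TGF-β;
myofibroblasts deposit ECM; MMP degrades
it. An alveolus with zero remaining AEC2 (healthy, damaged or senescent) is
counted as lost — with no progenitors the epithelium cannot be rebuilt.
Damaged and senescent cells do not undergo background apoptosis (their fate
is maturation or phagocytosis).

## 7. Engine

Each biological evaluation applies the behaviour categories in a fixed
order: secretion → bystander → maturation → phagocytosis → migration →
proliferation → differentiation → apoptosis; substance diffusion and influx
operations run on their own schedule between evaluations.

* **base mode**: 1 s diffusion step, 10 s biology/operations step — the
  reference schedule, used for cross-checks on short horizons;
* **coarse mode** (default, all long experiments): 1 h biological step with
  CFL-limited diffusion substeps. Per-hour hazards are converted to
  probabilities as `1 − exp(−rate·Δt)`, so the two modes share the same
  underlying rates; they agree within sampling noise on 6 h horizons.

Before `t = 0` the substance field is relaxed to its spatial steady state
with cells frozen as sources (400 h burn-in, two calibration rounds pinning
the Hill midpoints), so recorded concentrations start at baseline rather
than drifting toward it.

**Determinism.** A run is a pure function of (config, plan, seed): repeated
runs produce byte-identical outputs. Seeds for sweeps and replicate studies
are derived with `numpy.random.SeedSequence([base, dose_index, replicate])`
reduced below 2³¹.

**Early stop.** 1000-day endpoints support an early stop once (a) the
fraction has been delivered, (b) no damaged or senescent cell has existed
for 100 consecutive days, and (c) at least 400 days have elapsed. This is
sound for the survival endpoint because alveolus loss is irreversible (no
AEC2 source exists outside an alveolus) and recovery of a surviving alveolus
requires only healthy-cell dynamics whose fixed point is the homeostatic
one; empirically the last senescent cell disappears before day 80 even at
13.7 Gy, and ECM peaks near day 99 and declines thereafter, so day 400 with
a 100-day quiet window is far past every transient.

## 8. Analysis layer

* **Logistic fibrosis fit**: `ΔECM(D) = ECM_max / (1 + exp(4γ(1 − D/D₅₀)))`.
* **Probit (late) fit**: `A(D) = ½·A_max·(1 − erf(√π·γ·(1 − D/ED₅₀)))`,
  fitted above 5 Gy.
* **Critical-volume FSU survival**: an alveolus survives if at least one of
  its `N = 69` AEC2 survives: `S_alv(D) = 1 − (1 − exp(−αD − βD²))^N` with
  α/β fixed at 2 Gy, α fitted (degenerate all-survive data collapses to the
  α → 0 boundary).
* **RSI**: product of mean ECM increase and lost functioning volume
  (`n_lost · 4/3·π·r³`), a single fibrosis-burden index per dose.
* **verify_homeostasis**: flags any population or substance whose 60-day
  drift exceeds tolerance (default 20 %); the unirradiated model passes with
  all population drifts ≤ 10 %.

## 9. Calibration

Two layers of parameters exist.

**Derived (not tuned): homeostatic rates.** Lifespans set background
hazards (epithelium 120 d; macrophages, fibroblasts, myofibroblasts 30 d);
proliferation, differentiation and influx rates are then solved from the
population balance equations so that every compartment is stationary at the
Table-of-populations counts. Secretion rates are solved from the
diffusion–decay balance so that each substance's homeostatic mean matches
its declared baseline; Hill midpoints are pinned to those baselines.

**Tuned jointly (frozen on 2026-10-02): bystander and clearance.** The
bystander constant `k`, the phagocytic index and the MCP-1→monocyte influx
gain were tuned together against three behavioural targets: full recovery
(18/18 alveoli) at ≤ 4 Gy, ≈ 33 % alveolus survival at 13.7 Gy with full
senescence commitment, and senescent clearance completing well within one
simulated year. Intermediate working points that were rejected: clearance
capacity proportional to the senescent count (index-free) made inflammation
duration dose-independent; a large gain with index 5 cleared 13.7 Gy
senescence in ~10 days, leaving no room for a bystander wave. The frozen
values are `k = 1.2·10⁻³ h⁻²`, index 2, gain 3.0·10⁴ cells·h⁻¹ per (g/cm³),
with mesenchymal lifespans at 30 d to place the ECM peak at ≈ 3.3 months.
No parameter was adjusted after freezing.

Measured at the frozen defaults (coarse mode): 4 Gy → 18/18 recovered,
senescent gone by day 70; 13.7 Gy, full senescence → 34.3 % mean alveolus
survival over 6 seeds; 13.7 Gy, 20 % senescence → ≈ 61 %; duct-mean ECM at
13.7 Gy rises from 7.1·10⁻⁴ to a peak of 1.7·10⁻³ g/cm³ at day ≈ 99 and
declines to 1.3·10⁻³ by day 400.

## 10. Limitations

* **High-dose survival exceeds the LQ anchor.** Because per-alveolus damage
  draws are truncated at the 69 available AEC2, the realised surviving cell
  fraction at 17.6 Gy is ≈ 5.3 %, not the 1 % of the underlying LQ anchor.
  This is a structural property of capped Poisson damage, not a sampling
  artefact.
* **Ceiling on 20 %-senescence survival at 13.7 Gy.** At delivery,
  `P[Poisson(69·0.952) ≥ 69] ≈ 0.36` of alveoli lose all AEC2 instantly, so
  alveolus survival at 13.7 Gy cannot exceed ≈ 64 % under the anchor
  calibration regardless of downstream dynamics. Stochastic extinction of
  1–3-cell surviving clones (the proliferation boost is gated on local AEC1
  shortage, and AEC1 — untargeted by irradiation — take ~4 weeks to decay
  below the trigger) brings the measured value to ≈ 61 %. Values above that
  ceiling would require a different (shallower) survival curve at 13.7 Gy.
* **Residual ECM creep.** The unirradiated duct shows a slow, decelerating
  ECM rise above the burn-in baseline (an order of magnitude below the
  irradiated response). Late low-dose responses should therefore be judged
  against an unirradiated control run, as the analysis tests do.
* **Coarse grid and step.** The 4×4×4 substance grid resolves inter-alveolar
  gradients only coarsely, and the 1 h biological step linearises all
  hazards over an hour; both are validated against the 1 s/10 s base mode on
  short horizons only.
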