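"""Single-fraction irradiation: linear-quadratic survival and per-alveolus
Poisson damage with an apoptotic/senescent partition.

Cell survival follows the LQ model S(D) = exp(-alpha D - beta D^2).  The
default (alpha, beta) are calibrated from two anchor points of the
dose-survival relation used throughout: 95% survival at 0.6 Gy and 1% at
17.6 Gy, which pin down the linear 2x2 system alpha*D + beta*D^2 = -ln S.
Only healthy AEC2 are radiosensitive targets; the number hit in each
alveolus is Poisson with mean N_healthy * (1 - S(D)), truncated at the
available count.  A fraction ``senescent_fraction`` of the hit cells enters
the damaged state (and will mature to senescence); the rest are removed at
once (apoptosis).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .agents import BystanderParams, draw_damaged_timer
from .population import CellType, Phenotype, Population

__all__ = [
    "LQParams",
    "IrradiationPlan",
    "DEFAULT_ANCHORS",
    "lq_survival",
    "calibrate_lq",
    "apply_irradiation",
]

DEFAULT_ANCHORS = ((0.6, 0.95), (17.6, 0.01))


@dataclass(frozen=True)
class LQParams:
    alpha: float  # 1/Gy
    beta: float  # 1/Gy^2

    def __post_init__(self):
        if self.alpha <= 0 or self.beta < 0:
            raise ValueError("require alpha > 0 and beta >= 0")


@dataclass
class IrradiationPlan:
    dose_gy: float
    senescent_fraction: float = 1.0  # of the hit cells; the rest apoptose
    time_of_delivery_h: float = 0.0

    def __post_init__(self):
        if self.dose_gy < 0:
            raise ValueError("dose must be non-negative")
        if not 0.0 <= self.senescent_fraction <= 1.0:
            raise ValueError("senescent_fraction must lie in [0, 1]")


def lq_survival(dose_gy: float, params: LQParams) -> float:
    """S(D) = exp(-alpha D - beta D^2), in (0, 1]."""
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    return float(np.exp(-params.alpha * dose_gy - params.beta * dose_gy**2))


def calibrate_lq(anchors=DEFAULT_ANCHORS) -> LQParams:
    """Solve alpha, beta exactly from two (dose, survival) anchor points."""
    (d1, s1), (d2, s2) = anchors
    if d1 <= 0 or d2 <= 0 or d1 == d2:
        raise ValueError("anchors need two distinct positive doses")
    if not (0 < s1 < 1 and 0 < s2 < 1):
        raise ValueError("anchor survivals must lie in (0, 1)")
    a = np.array([[d1, d1**2], [d2, d2**2]])
    b = -np.log([s1, s2])
    alpha, beta = np.linalg.solve(a, b)
    if abs(beta) < 1e-15 * max(abs(alpha), 1.0):
        beta = 0.0  # exact-exponential anchors: clamp float noise
    if alpha <= 0 or beta < 0:
        raise ValueError(f"anchors give non-physical LQ parameters: alpha={alpha:g}, beta={beta:g}")
    return LQParams(alpha=float(alpha), beta=float(beta))


@dataclass
class DamageReport:
    """Per-alveolus damage bookkeeping from one delivery."""

    alveolus_id: np.ndarray
    n_initial: np.ndarray
    n_damaged: np.ndarray
    n_apoptosed: np.ndarray
    n_to_senescent_path: np.ndarray
    dose_gy: float = 0.0
    survival: float = 1.0

    def as_dict(self) -> dict:
        return {
            "alveolus_id": self.alveolus_id.tolist(),
            "n_initial": self.n_initial.tolist(),
            "n_damaged": self.n_damaged.tolist(),
            "n_apoptosed": self.n_apoptosed.tolist(),
            "n_to_senescent_path": self.n_to_senescent_path.tolist(),
        }


def apply_irradiation(
    pop: Population,
    plan: IrradiationPlan,
    params: LQParams,
    rng: np.random.Generator,
    bystander: BystanderParams | None = None,
) -> DamageReport:
    """Deliver one fraction to the population, mutating it in place.

    Per alveolus, n_damaged ~ Poisson(N_healthy * (1 - S)), truncated at the
    available healthy AEC2; the hit cells are chosen uniformly without
    replacement.  Binomial(n_damaged, senescent_fraction) of them enter the
    damaged state with a maturation timer; the rest are removed immediately.
    """
    bystander = bystander or BystanderParams()
    s = lq_survival(plan.dose_gy, params)
    n_alv = pop.duct.n_alveoli
    report = DamageReport(
        alveolus_id=np.arange(n_alv),
        n_initial=pop.healthy_aec2_per_alveolus().copy(),
        n_damaged=np.zeros(n_alv, dtype=int),
        n_apoptosed=np.zeros(n_alv, dtype=int),
        n_to_senescent_path=np.zeros(n_alv, dtype=int),
        dose_gy=plan.dose_gy,
        survival=s,
    )
    if plan.dose_gy == 0.0:
        return report
    healthy = pop.rows(CellType.AEC2, Phenotype.HEALTHY)
    to_remove = []
    for alv in range(n_alv):
        rows = healthy[pop.alveolus[healthy] == alv]
        n_avail = rows.size
        if n_avail == 0:
            continue
        n_dam = min(int(rng.poisson(n_avail * (1.0 - s))), n_avail)
        report.n_damaged[alv] = n_dam
        if n_dam == 0:
            continue
        hit = rng.choice(rows, size=n_dam, replace=False)
        n_sen = int(rng.binomial(n_dam, plan.senescent_fraction))
        report.n_to_senescent_path[alv] = n_sen
        report.n_apoptosed[alv] = n_dam - n_sen
        sen_path = hit[:n_sen]
        pop.phenotype[sen_path] = int(Phenotype.DAMAGED)
        pop.tau[sen_path] = 0.0
        pop.damaged_timer[sen_path] = draw_damaged_timer(bystander, rng, n_sen)
        to_remove.append(hit[n_sen:])
    if to_remove:
        pop.remove(np.concatenate(to_remove))
    return report
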