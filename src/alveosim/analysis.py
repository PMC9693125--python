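"""Dose-response and severity analysis of simulation outputs.

Derived quantities:

* ``delta_ecm`` — the whole-space mean ECM increase over the pre-irradiation
  baseline, the model's surrogate for CT density change.
* Early (3-month) sigmoid:  dECM(D) = dECM_max / (1 + exp(4 g (1 - D/D50)))
* Late (1000-day) probit:   dECM(D) = A/2 * (1 - erf(sqrt(pi) g (1 - D/ED50)))
  with doses below 5 Gy excluded (late changes there are negligible).
* Critical-volume functional-subunit survival:
  P_surv(D) = 1 - (1 - exp(-a D - b D^2))^N  with b = a / (a/b ratio), the
  probability that at least one of the N stem cells in an alveolus survives.
* RSI — the fibrosis severity index: mean ECM increase times the lost
  functioning volume of the depleted alveoli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import erf

from .geometry import alveolus_volume_cm3

__all__ = [
    "LogisticFit",
    "ProbitFit",
    "FsuSurvivalModel",
    "RsiResult",
    "delta_ecm",
    "logistic_curve",
    "probit_curve",
    "fit_logistic",
    "fit_probit",
    "fsu_survival_predict",
    "fit_fsu_survival",
    "rsi",
    "verify_homeostasis",
]


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class LogisticFit:
    ecm_max: float  # g/cm^3
    gamma: float
    d50: float  # Gy
    residual_norm: float = 0.0

    def __post_init__(self):
        if self.ecm_max <= 0 or self.d50 <= 0:
            raise ValueError("require ecm_max > 0 and d50 > 0")

    def predict(self, dose):
        return logistic_curve(np.asarray(dose, dtype=float), self.ecm_max, self.gamma, self.d50)


@dataclass(frozen=True)
class ProbitFit:
    a_max: float  # g/cm^3
    gamma: float
    ed50: float  # Gy
    residual_norm: float = 0.0

    def __post_init__(self):
        if self.a_max <= 0 or self.ed50 <= 0:
            raise ValueError("require a_max > 0 and ed50 > 0")

    def predict(self, dose):
        return probit_curve(np.asarray(dose, dtype=float), self.a_max, self.gamma, self.ed50)


@dataclass(frozen=True)
class FsuSurvivalModel:
    alpha: float  # 1/Gy
    alpha_beta_ratio: float = 2.0  # Gy
    n_aec2: int = 69

    @property
    def beta(self) -> float:
        return self.alpha / self.alpha_beta_ratio

    def predict(self, dose):
        return fsu_survival_predict(dose, self)


@dataclass(frozen=True)
class RsiResult:
    delta_ecm_mean: float  # g/cm^3
    delta_v: float  # cm^3 of lost functioning volume
    rsi: float  # g


# ---------------------------------------------------------------------------
# time-series reduction


def delta_ecm(series: pd.DataFrame, timepoint_days: float, baseline: float) -> float:
    """Mean-ECM increase over baseline at the record nearest the timepoint."""
    t_h = timepoint_days * 24.0
    if t_h > series["t_hours"].iloc[-1] + 1e-9:
        raise ValueError(
            f"timepoint {timepoint_days:g} d beyond the series "
            f"({series['t_hours'].iloc[-1] / 24.0:g} d)"
        )
    i = (series["t_hours"] - t_h).abs().idxmin()
    return float(series["conc_ECM"].iloc[i] - baseline)


# ---------------------------------------------------------------------------
# sigmoid fits


def logistic_curve(dose, ecm_max, gamma, d50):
    return ecm_max / (1.0 + np.exp(4.0 * gamma * (1.0 - dose / d50)))


def probit_curve(dose, a_max, gamma, ed50):
    return 0.5 * a_max * (1.0 - erf(np.sqrt(np.pi) * gamma * (1.0 - dose / ed50)))


def _multistart_fit(curve, doses, values, p0_list, bounds):
    best = None
    errors = []
    for p0 in p0_list:
        try:
            popt, _ = curve_fit(curve, doses, values, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError) as e:  # non-convergence for this start
            errors.append(str(e))
            continue
        res = float(np.linalg.norm(curve(doses, *popt) - values))
        if best is None or res < best[1]:
            best = (popt, res)
    if best is None:
        raise RuntimeError(f"sigmoid fit failed from all starts: {errors}")
    return best


def _starts(doses, values):
    """Data-driven multistart heuristics: amplitude from the max response,
    midpoint from the dose nearest half-max, steepness around 1."""
    vmax = max(float(np.max(values)), 1e-30)
    half_idx = int(np.argmin(np.abs(values - 0.5 * vmax)))
    d_half = float(np.clip(doses[half_idx], 1e-3, None))
    d_mid = float(np.clip(np.median(doses), 1e-3, None))
    return [
        (vmax, 1.0, d_half),
        (vmax, 0.5, d_half),
        (vmax, 2.0, d_half),
        (1.2 * vmax, 1.0, d_mid),
        (vmax, 1.0, d_mid),
    ]


def fit_logistic(doses, delta_ecms) -> LogisticFit:
    """Least-squares early-response sigmoid; needs points on both flanks."""
    doses = np.asarray(doses, dtype=float)
    values = np.asarray(delta_ecms, dtype=float)
    if doses.size < 4:
        raise ValueError("need at least 4 dose points")
    bounds = ([1e-30, 1e-3, 1e-3], [np.inf, 100.0, 1e3])
    popt, res = _multistart_fit(logistic_curve, doses, values, _starts(doses, values), bounds)
    return LogisticFit(ecm_max=popt[0], gamma=popt[1], d50=popt[2], residual_norm=res)


def fit_probit(doses, delta_ecms, exclude_below_gy: float = 5.0) -> ProbitFit:
    """Least-squares late-response probit, dropping doses below 5 Gy."""
    doses = np.asarray(doses, dtype=float)
    values = np.asarray(delta_ecms, dtype=float)
    keep = doses >= exclude_below_gy
    doses, values = doses[keep], values[keep]
    if doses.size < 4:
        raise ValueError("need at least 4 retained dose points (>= exclusion threshold)")
    bounds = ([1e-30, 1e-3, 1e-3], [np.inf, 100.0, 1e3])
    popt, res = _multistart_fit(probit_curve, doses, values, _starts(doses, values), bounds)
    return ProbitFit(a_max=popt[0], gamma=popt[1], ed50=popt[2], residual_norm=res)


# ---------------------------------------------------------------------------
# critical-volume FSU survival


def fsu_survival_predict(dose, model: FsuSurvivalModel):
    """1 - (1 - S_cell)^N: an alveolus survives iff any stem cell survives."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    s_cell = np.exp(-model.alpha * d - model.beta * d**2)
    out = 1.0 - (1.0 - s_cell) ** model.n_aec2
    return float(out) if np.isscalar(dose) else out


def fit_fsu_survival(
    doses, survival_fractions, alpha_beta_ratio: float = 2.0, n_aec2: int = 69
):
    """Fit alpha (ratio and N fixed); report per-dose residuals.

    Returns (model, report): the report lists simulated - fitted residuals
    per dose with a ``high_dose_tail`` flag on the upper third of the dose
    range, where the critical-volume curve is expected to underestimate
    simulated survival (repopulation is not compensated by bystander kill
    in that regime).
    """
    doses = np.asarray(doses, dtype=float)
    values = np.asarray(survival_fractions, dtype=float)
    if doses.size < 3:
        raise ValueError("need at least 3 dose points")

    def curve(d, alpha):
        m = FsuSurvivalModel(alpha=alpha, alpha_beta_ratio=alpha_beta_ratio, n_aec2=n_aec2)
        return fsu_survival_predict(d, m)

    try:
        popt, _ = curve_fit(curve, doses, values, p0=(0.1,), bounds=(0.0, 10.0), maxfev=20000)
    except (RuntimeError, ValueError) as e:
        raise RuntimeError(f"FSU survival fit failed: {e}") from e
    alpha = float(popt[0])
    # degenerate data (e.g. survival = 1 everywhere): a whole interval of
    # alphas fits equally well; report the boundary value in that case
    if np.linalg.norm(curve(doses, 0.0) - values) <= np.linalg.norm(
        curve(doses, alpha) - values
    ) + 1e-12:
        alpha = 0.0
    model = FsuSurvivalModel(alpha=alpha, alpha_beta_ratio=alpha_beta_ratio, n_aec2=n_aec2)
    fitted = model.predict(doses)
    cut = doses.min() + 2.0 * (doses.max() - doses.min()) / 3.0
    report = pd.DataFrame(
        {
            "dose_gy": doses,
            "simulated": values,
            "fitted": fitted,
            "residual": values - fitted,
            "high_dose_tail": doses >= cut,
        }
    )
    return model, report


# ---------------------------------------------------------------------------
# RILF severity index


def rsi(delta_ecm_mean: float, n_depleted_alveoli: int, alveolus_radius_um: float) -> RsiResult:
    """RSI = mean ECM increase x lost functioning volume (whole alveoli)."""
    if delta_ecm_mean < 0 or n_depleted_alveoli < 0:
        raise ValueError("inputs must be non-negative")
    delta_v = n_depleted_alveoli * alveolus_volume_cm3(alveolus_radius_um)
    return RsiResult(
        delta_ecm_mean=delta_ecm_mean, delta_v=delta_v, rsi=delta_ecm_mean * delta_v
    )


# ---------------------------------------------------------------------------
# homeostasis verification


POPULATION_COLUMNS = (
    "n_AEC1",
    "n_AEC2_healthy",
    "n_M1",
    "n_M2",
    "n_Fibroblast",
    "n_Myofibroblast",
)


def verify_homeostasis(series: pd.DataFrame, tolerance: float = 0.2):
    """Check an unirradiated series for population and substance stability.

    Fails if any population's mean over the final week deviates from its
    initial value by more than ``tolerance`` (relative), or if any substance
    mean drifts monotonically (weekly means all moving one way) by more than
    ``tolerance`` of its initial level.  Returns (passed, report DataFrame).
    """
    t = series["t_hours"].to_numpy()
    if t[-1] < 28 * 24.0:
        raise ValueError("need at least 28 days of records")
    last_week = series[t >= t[-1] - 7 * 24.0]
    rows = []
    passed = True
    for col in POPULATION_COLUMNS:
        if col not in series:
            continue
        initial = float(series[col].iloc[0])
        mean_final = float(last_week[col].mean())
        drift = (mean_final - initial) / initial if initial else 0.0
        ok = abs(drift) <= tolerance
        passed &= ok
        rows.append({"quantity": col, "initial": initial, "final_week_mean": mean_final,
                     "relative_drift": drift, "ok": ok})
    week = (t // (7 * 24.0)).astype(int)
    for col in [c for c in series.columns if c.startswith("conc_")]:
        weekly = series.groupby(week)[col].mean().to_numpy()
        initial = weekly[0]
        scale = abs(initial) if initial else max(abs(weekly).max(), 1e-300)
        diffs = np.diff(weekly)
        monotone = bool(diffs.size) and (np.all(diffs > 0) or np.all(diffs < 0))
        drift = (weekly[-1] - initial) / scale
        ok = not (monotone and abs(drift) > tolerance)
        passed &= ok
        rows.append({"quantity": col, "initial": initial, "final_week_mean": weekly[-1],
                     "relative_drift": drift, "ok": ok})
    return passed, pd.DataFrame(rows)
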