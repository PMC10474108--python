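"""Reduced PBPK block: antibody exposure in plasma, CSF, ISF and synaptic cleft.

The full physiological antibody-distribution models (per-tissue vascular /
endosomal spaces, FcRn recycling) are not identifiable from the data the
clinical programmes published, which are plasma concentration-time profiles,
terminal half-lives and CSF:plasma exposure ratios.  This module therefore
uses exactly those observables as its parameterization:

* plasma kinetics: biexponential disposition fitted to (or specified from)
  the reported profiles, superposed over an i.v. bolus regimen;
* brain entry: first-order tracking of plasma with configurable CSF/plasma
  and ISF/plasma exposure ratios (printed windows 0.1-0.4% and 0.07-0.3%),
  a lag, an optional first-order ISF sink standing in for futile microglial
  FcgR binding, and a static tortuosity attenuation;
* synaptic cleft: flow coupling to ISF at ``Q_isf_cleft``; when run inside
  the full synapse model the cleft antibody is additionally consumed
  stoichiometrically by protein capture.

All internal state is nM and hours; doses convert mg -> nmol via the IgG
molecular weight (150 kDa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .geometry import BrainGeometry, ValidationError

IGG_MW_KDA = 150.0
LN2 = math.log(2.0)


class FittingError(RuntimeError):
    """Raised when a pharmacokinetic fit cannot be performed."""


def mg_to_nmol(dose_mg: float, mw_kda: float = IGG_MW_KDA) -> float:
    """Convert an antibody dose in mg to nmol (mw in kDa = kg/mol)."""
    return dose_mg / mw_kda * 1e3


@dataclass(frozen=True)
class DoseRegimen:
    """An i.v. dose schedule.

    Doses may be flat (``dose_mg``) or weight-based (``dose_mg_per_kg``
    with ``body_weight_kg``, default 70 kg per the trial conversions).
    ``interval_h`` of 672 h corresponds to Q4W dosing.
    """

    dose_mg: float | None = None
    dose_mg_per_kg: float | None = None
    body_weight_kg: float = 70.0
    n_doses: int = 1
    interval_h: float = 672.0
    infusion_duration_h: float = 0.0
    trial_duration_weeks: float = 52.0

    def __post_init__(self) -> None:
        if (self.dose_mg is None) == (self.dose_mg_per_kg is None):
            raise ValidationError("specify exactly one of dose_mg / dose_mg_per_kg")
        if self.flat_dose_mg < 0:
            raise ValidationError("dose must be non-negative")
        if self.n_doses < 1 or self.interval_h <= 0:
            raise ValidationError("regimen needs >= 1 dose and a positive interval")
        if self.infusion_duration_h < 0:
            raise ValidationError("infusion duration must be non-negative")
        if self.n_doses * self.interval_h > self.duration_h + self.interval_h:
            raise ValidationError("regimen extends beyond the trial duration")

    @property
    def flat_dose_mg(self) -> float:
        if self.dose_mg is not None:
            return self.dose_mg
        return self.dose_mg_per_kg * self.body_weight_kg

    @property
    def dose_nmol(self) -> float:
        return mg_to_nmol(self.flat_dose_mg)

    @property
    def duration_h(self) -> float:
        return self.trial_duration_weeks * 7 * 24

    @property
    def dose_times(self) -> np.ndarray:
        return np.arange(self.n_doses) * self.interval_h

    def with_dose_mg(self, dose_mg: float) -> "DoseRegimen":
        return replace(self, dose_mg=dose_mg, dose_mg_per_kg=None)


@dataclass(frozen=True)
class PlasmaPKParams:
    """Biexponential plasma disposition of an IgG antibody.

    Concentration after a unit bolus D (nmol):
        C(t) = D / V_central * [f_dist exp(-l_f t) + (1 - f_dist) exp(-l_s t)]
    with l_s = ln2 / half_life_h the terminal phase and l_f = ln2 /
    distribution_half_life_h the (faster) distribution phase.
    """

    half_life_h: float
    central_volume_l: float = 3.1
    distribution_half_life_h: float = 24.0
    distribution_fraction: float = 0.3
    mw_kda: float = IGG_MW_KDA

    def __post_init__(self) -> None:
        if self.half_life_h <= 0 or self.central_volume_l <= 0:
            raise ValidationError("half-life and central volume must be positive")
        if not 0 <= self.distribution_fraction < 1:
            raise ValidationError("distribution fraction must lie in [0, 1)")
        if self.distribution_half_life_h >= self.half_life_h:
            raise ValidationError("distribution phase must be faster than terminal phase")

    @property
    def terminal_rate(self) -> float:
        return LN2 / self.half_life_h

    @property
    def distribution_rate(self) -> float:
        return LN2 / self.distribution_half_life_h

    def unit_impulse(self, t: np.ndarray) -> np.ndarray:
        """Plasma concentration (nM) per nmol of bolus dose at t=0."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        pos = t >= 0
        f = self.distribution_fraction
        out[pos] = (
            f * np.exp(-self.distribution_rate * t[pos])
            + (1 - f) * np.exp(-self.terminal_rate * t[pos])
        ) / self.central_volume_l
        return out

    def concentration(self, t, regimen: DoseRegimen) -> np.ndarray:
        """Plasma concentration (nM) under a multi-dose regimen (superposition)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        dose = regimen.dose_nmol
        total = np.zeros_like(t)
        if dose == 0:
            return total
        # infusions are approximated by splitting the dose into sub-boluses
        n_sub = 1 if regimen.infusion_duration_h == 0 else 20
        for t0 in regimen.dose_times:
            for k in range(n_sub):
                tk = t0 + (k + 0.5) * regimen.infusion_duration_h / n_sub if n_sub > 1 else t0
                total += dose / n_sub * self.unit_impulse(t - tk)
        return total

    def auc_per_dose(self) -> float:
        """AUC (nM*h) of a single unit (1 nmol) bolus, integrated to infinity."""
        f = self.distribution_fraction
        return (f / self.distribution_rate + (1 - f) / self.terminal_rate) / self.central_volume_l


@dataclass(frozen=True)
class BrainTransferParams:
    """Plasma -> brain transfer of antibody, constrained to the printed windows.

    ``csf_plasma_ratio`` and ``isf_plasma_ratio`` are steady-state exposure
    ratios; brain concentrations track plasma first-order with time constant
    ``lag_h``.  ``microglia_sink_rate`` is a first-order ISF loss standing in
    for futile FcgR binding / internalization in microglia;
    ``tortuosity_attenuation`` statically scales ISF availability.
    """

    csf_plasma_ratio: float = 0.0025
    isf_plasma_ratio: float = 0.002
    lag_h: float = 24.0
    microglia_sink_rate: float = 0.0
    tortuosity_attenuation: float = 1.0

    def __post_init__(self) -> None:
        if not 0.001 <= self.csf_plasma_ratio <= 0.004:
            raise ValidationError("csf_plasma_ratio outside the admissible window 0.001-0.004")
        if not 0.0007 <= self.isf_plasma_ratio <= 0.003:
            raise ValidationError("isf_plasma_ratio outside the admissible window 0.0007-0.003")
        if self.isf_plasma_ratio > self.csf_plasma_ratio:
            raise ValidationError("ISF/plasma ratio must not exceed CSF/plasma ratio")
        if self.lag_h <= 0:
            raise ValidationError("lag must be positive")
        if self.microglia_sink_rate < 0:
            raise ValidationError("microglia sink rate must be non-negative")
        if not 0 < self.tortuosity_attenuation <= 1:
            raise ValidationError("tortuosity attenuation must lie in (0, 1]")

    @property
    def effective_isf_ratio(self) -> float:
        """Realized steady-state ISF/plasma ratio including sink and tortuosity."""
        k = 1.0 / self.lag_h
        return self.isf_plasma_ratio * self.tortuosity_attenuation * k / (k + self.microglia_sink_rate)


@dataclass
class ExposureResult:
    """Antibody concentration time courses per compartment (nM)."""

    time_h: np.ndarray
    plasma_nM: np.ndarray
    csf_nM: np.ndarray
    isf_nM: np.ndarray
    cleft_nM: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time_h,
                "plasma_nM": self.plasma_nM,
                "csf_nM": self.csf_nM,
                "isf_nM": self.isf_nM,
                "cleft_nM": self.cleft_nM,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate_antibody_exposure(
    pk: PlasmaPKParams,
    transfer: BrainTransferParams,
    geometry: BrainGeometry,
    regimen: DoseRegimen,
    *,
    n_points: int = 2000,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> ExposureResult:
    """Simulate antibody concentrations in plasma, CSF, ISF and cleft.

    Plasma is analytic (dose superposition).  CSF and ISF track plasma
    first-order toward their exposure ratios; the cleft is flow-coupled to
    the ISF at ``Q_isf_cleft`` with no protein present (the coupled case
    lives in :mod:`cleftqsp.trials`).
    """
    if regimen.flat_dose_mg < 0:
        raise ValidationError("dose must be non-negative")
    t_end = regimen.duration_h
    if regimen.dose_times[-1] > t_end:
        raise ValidationError("regimen longer than integration horizon")

    k_lag = 1.0 / transfer.lag_h
    k_cleft = geometry.Q_isf_cleft / geometry.V_cleft_total

    def rhs(t, y):
        cp = pk.concentration(t, regimen)[0]
        a_csf, a_isf, a_cleft = y
        d_csf = k_lag * (transfer.csf_plasma_ratio * cp - a_csf)
        d_isf = (
            k_lag * (transfer.isf_plasma_ratio * transfer.tortuosity_attenuation * cp - a_isf)
            - transfer.microglia_sink_rate * a_isf
        )
        d_cleft = k_cleft * (a_isf - a_cleft)
        return [d_csf, d_isf, d_cleft]

    t_eval = np.linspace(0.0, t_end, n_points)
    if regimen.dose_nmol == 0:
        zeros = np.zeros_like(t_eval)
        return ExposureResult(t_eval, zeros, zeros.copy(), zeros.copy(), zeros.copy())

    # integrate piecewise between dose times so the solver never steps across
    # a bolus discontinuity
    breaks = np.unique(np.concatenate([regimen.dose_times, [0.0, t_end]]))
    breaks = breaks[(breaks >= 0) & (breaks <= t_end)]
    y0 = [0.0, 0.0, 0.0]
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for a, b in zip(breaks[:-1], breaks[1:]):
        seg_eval = t_eval[(t_eval >= a) & (t_eval <= b)]
        seg_eval = np.unique(np.concatenate([[a], seg_eval, [b]]))
        sol = solve_ivp(
            rhs, (a, b), y0, method="LSODA", t_eval=seg_eval, rtol=rtol, atol=atol
        )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"exposure integration failed: {sol.message}")
        ts.append(sol.t)
        ys.append(sol.y)
        y0 = sol.y[:, -1]
    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    # drop duplicated segment endpoints
    t_all, idx = np.unique(t_all, return_index=True)
    y_all = y_all[:, idx]
    plasma = pk.concentration(t_all, regimen)
    return ExposureResult(t_all, plasma, y_all[0], y_all[1], y_all[2])


# ---------------------------------------------------------------------------
# Plasma PK fitting (Model / Results pair)
# ---------------------------------------------------------------------------


@dataclass
class PlasmaPKResults:
    """Results of a biexponential plasma-PK fit."""

    params: PlasmaPKParams
    residual_log: np.ndarray
    n_obs: int
    dose: DoseRegimen

    @property
    def half_life_h(self) -> float:
        return self.params.half_life_h

    @property
    def sse_log(self) -> float:
        return float(np.sum(self.residual_log**2))

    def summary(self) -> str:
        p = self.params
        lines = [
            "Plasma PK fit (biexponential disposition)",
            f"  n observations        : {self.n_obs}",
            f"  terminal half-life    : {p.half_life_h:.1f} h",
            f"  central volume        : {p.central_volume_l:.2f} L",
            f"  distribution t1/2     : {p.distribution_half_life_h:.1f} h",
            f"  distribution fraction : {p.distribution_fraction:.3f}",
            f"  SSE (log conc)        : {self.sse_log:.4g}",
        ]
        return "\n".join(lines)


class PlasmaPKModel:
    """Fit biexponential plasma kinetics to observed (time, concentration) data.

    Parameters
    ----------
    observations
        Sequence of ``(time_h, conc_nM)`` pairs after the first dose.
    dose
        The administered regimen (a single dose for phase-1 style fits).
    """

    def __init__(self, observations, dose: DoseRegimen):
        obs = np.asarray(list(observations), dtype=float)
        if obs.ndim != 2 or obs.shape[1] != 2 or obs.shape[0] < 4:
            raise FittingError("need at least 4 (time, concentration) observations")
        if np.any(np.diff(obs[:, 0]) <= 0):
            raise ValidationError("observation times must be strictly increasing")
        if np.any(obs[:, 1] <= 0):
            raise ValidationError("observed concentrations must be positive")
        self.obs = obs
        self.dose = dose

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, dose: DoseRegimen) -> "PlasmaPKModel":
        """Build from a frame with columns ``time_h`` and ``conc_nM``."""
        return cls(frame[["time_h", "conc_nM"]].to_numpy(), dose)

    def _predict_log(self, theta: np.ndarray) -> np.ndarray:
        log_hl, log_vc, logit_f, log_hl_f = theta
        f = 1.0 / (1.0 + np.exp(-logit_f))
        pk = PlasmaPKParams(
            half_life_h=np.exp(log_hl),
            central_volume_l=np.exp(log_vc),
            distribution_fraction=f,
            distribution_half_life_h=np.exp(log_hl_f),
        )
        pred = pk.concentration(self.obs[:, 0], self.dose)
        return np.log(np.clip(pred, 1e-30, None))

    def fit(self) -> PlasmaPKResults:
        """Least-squares fit on log-concentration; recovers the terminal phase."""
        t, c = self.obs[:, 0], self.obs[:, 1]
        logc = np.log(c)
        # terminal slope from the last half of the data
        tail = slice(len(t) // 2, None)
        slope = np.polyfit(t[tail], logc[tail], 1)[0]
        hl0 = LN2 / max(-slope, 1e-6)
        hl0 = float(np.clip(hl0, 10.0, 5e4))
        vc0 = self.dose.dose_nmol / np.exp(logc[0])
        theta0 = np.array([np.log(hl0), np.log(max(vc0, 0.1)), -1.0, np.log(min(24.0, hl0 / 4))])

        def resid(theta):
            if np.exp(theta[3]) >= np.exp(theta[0]):
                return np.full(len(t), 1e3)
            return self._predict_log(theta) - logc

        sol = least_squares(resid, theta0, method="lm", max_nfev=5000)
        log_hl, log_vc, logit_f, log_hl_f = sol.x
        params = PlasmaPKParams(
            half_life_h=float(np.exp(log_hl)),
            central_volume_l=float(np.exp(log_vc)),
            distribution_fraction=float(1.0 / (1.0 + np.exp(-logit_f))),
            distribution_half_life_h=float(np.exp(log_hl_f)),
        )
        return PlasmaPKResults(params=params, residual_log=sol.fun, n_obs=len(t), dose=self.dose)


def fit_plasma_pk(observations, dose: DoseRegimen) -> PlasmaPKResults:
    """Functional wrapper over :class:`PlasmaPKModel`."""
    return PlasmaPKModel(observations, dose).fit()
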