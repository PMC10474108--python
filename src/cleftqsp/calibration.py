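"""Calibration: unit conversions, secretion tuning and uptake fitting.

Secretion rates are the one disease parameter the clinical literature pins
directly: at steady state the cleft efflux chain must reproduce the measured
free CSF monomer level (tau 3 pM healthy/PSP, 6.7 pM AD; aSyn 112 pM) with
the assumed oligomer:monomer ratio.  ``calibrate_secretion`` root-finds the
two secretion rates against those targets and reports the implied ISF level
for comparison with the microdialysis ranges.

Uptake parameters (receptor kinetics, internalization, pinocytosis) are fit
to in-vitro uptake experiments; here `UptakeModel` fits the reduced
cell-culture bath model (constant extracellular concentration, no secretion)
to such data, and :mod:`cleftqsp.fixtures` generates synthetic surrogates
with the same structure for parameter-recovery studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .cleft import SynapseModel
from .geometry import BrainGeometry, ValidationError
from .presets import DiseaseSpec
from .species import CleftState


def mass_to_molar(level_pg_ml: float, mw_kda: float) -> float:
    """Convert a fluid level in pg/ml to pM given the protein MW in kDa.

    1 pg/ml divided by 1 kg/mol is exactly 1 pM, so pM = (pg/ml) / kDa.
    """
    if mw_kda <= 0:
        raise ValidationError("molecular weight must be positive")
    if level_pg_ml < 0:
        raise ValidationError("level must be non-negative")
    return level_pg_ml / mw_kda


def molar_to_mass(level_pM: float, mw_kda: float) -> float:
    """Inverse of :func:`mass_to_molar`."""
    if mw_kda <= 0:
        raise ValidationError("molecular weight must be positive")
    return level_pM * mw_kda


@dataclass(frozen=True)
class CalibrationTargets:
    """Steady-state clinical levels the disease model must reproduce."""

    csf_monomer_pM: float
    oligomer_fraction: float
    isf_monomer_range_pM: tuple[float, float] = (0.0, np.inf)
    protein_mw_kda: float = 60.0

    def __post_init__(self) -> None:
        if self.csf_monomer_pM <= 0:
            raise ValidationError("csf_monomer_pM must be positive")
        if not 0 < self.oligomer_fraction <= 1:
            raise ValidationError("oligomer_fraction must lie in (0, 1]")

    @classmethod
    def from_disease(cls, disease: DiseaseSpec) -> "CalibrationTargets":
        return cls(
            csf_monomer_pM=disease.csf_monomer_pM,
            oligomer_fraction=disease.oligomer_fraction,
            isf_monomer_range_pM=disease.isf_monomer_range_pM,
            protein_mw_kda=disease.protein_mw_kda,
        )


@dataclass
class CalibrationResult:
    """Calibrated secretion rates and the implied compartment levels."""

    secretion_rates: np.ndarray          # nM/h per species
    steady_state: CleftState
    csf_pM: np.ndarray                   # per species
    isf_pM: np.ndarray                   # per species
    targets: CalibrationTargets
    model: SynapseModel

    @property
    def csf_monomer_pM(self) -> float:
        return float(self.csf_pM[0])

    @property
    def isf_monomer_pM(self) -> float:
        return float(self.isf_pM[0])

    def summary(self) -> str:
        lo, hi = self.targets.isf_monomer_range_pM
        lines = [
            "Secretion calibration",
            f"  S_monomer  : {self.secretion_rates[0]:.4g} nM/h",
            f"  S_oligomer : {self.secretion_rates[1]:.4g} nM/h",
            f"  CSF monomer: {self.csf_monomer_pM:.4g} pM (target {self.targets.csf_monomer_pM} pM)",
            f"  ISF monomer: {self.isf_monomer_pM:.4g} pM (microdialysis range {lo}-{hi} pM)",
            f"  cleft free monomer : {self.steady_state.T[0]:.4g} nM",
            f"  cleft free oligomer: {self.steady_state.T[1]:.4g} nM",
        ]
        return "\n".join(lines)


def _chain_levels(model: SynapseModel, state: CleftState, geometry: BrainGeometry):
    """Steady-state ISF and CSF protein levels (pM) implied by cleft efflux."""
    kout = np.array([s.cleft_efflux_rate for s in model.species])
    flux = kout * state.T * geometry.V_cleft_total      # nmol/h
    isf_nM = flux / geometry.Q_isf_csf
    csf_nM = flux / geometry.Q_csf_clear
    return isf_nM * 1e3, csf_nM * 1e3


def steady_state_levels(model: SynapseModel, geometry: BrainGeometry):
    """Antibody-free steady state plus implied ISF/CSF levels."""
    ss = model.steady_state()
    isf, csf = _chain_levels(model, ss, geometry)
    return ss, isf, csf


def calibrate_secretion(
    disease: DiseaseSpec,
    targets: CalibrationTargets | None = None,
    geometry: BrainGeometry | None = None,
    *,
    tol: float = 1e-3,
    max_iter: int = 60,
) -> CalibrationResult:
    """Tune secretion rates so steady-state CSF monomer hits the target.

    The monomer secretion S_0 is root-found against the steady-state CSF
    monomer level; the oligomer secretion S_1 is set from the assumed
    oligomer:monomer secretion ratio.  Relative tolerance ``tol`` (default
    0.1%) applies to the CSF target.
    """
    geometry = geometry or BrainGeometry()
    targets = targets or CalibrationTargets.from_disease(disease)

    def build(s0: float, s1: float) -> SynapseModel:
        return SynapseModel(
            disease.species((s0, s1)),
            disease.receptor_pool(),
            pinocytosis=disease.pinocytosis,
            geometry=geometry,
        )

    target_csf = targets.csf_monomer_pM

    # initial secretion guess from the linear chain with no receptor sink
    kout = np.log(2.0) / disease.cleft_half_life_h
    T0_goal = target_csf * 1e-3 * geometry.Q_csf_clear / (kout * geometry.V_cleft_total)
    s0 = T0_goal * kout * 2.0
    warm: CleftState | None = None

    def csf_of(s0: float) -> tuple[float, CleftState, SynapseModel]:
        # oligomer secretion is slaved to the monomer rate by the assumed
        # secretion ratio (tau 100:1, aSyn oligomer = 25-30% of monomer)
        model = build(s0, targets.oligomer_fraction * s0)
        ss = model.steady_state(initial=warm)
        _, csf = _chain_levels(model, ss, geometry)
        return float(csf[0]), ss, model

    # 1-D root solve on log S_0 against the log CSF error; the map is smooth
    # and monotone with slope near 1 away from receptor saturation
    from scipy.optimize import root_scalar

    state = {}

    def err_of(log_s0: float) -> float:
        nonlocal warm
        csf, ss, model = csf_of(float(np.exp(np.clip(log_s0, -60, 60))))
        warm = ss
        state.update(csf=csf, ss=ss, model=model, s0=float(np.exp(log_s0)))
        return np.log(csf / target_csf)

    x0 = np.log(s0)
    e0 = err_of(x0)
    x1 = x0 - np.clip(e0, -2, 2)
    sol = root_scalar(err_of, x0=x0, x1=x1, method="secant",
                      xtol=1e-10, maxiter=max_iter)
    err = err_of(sol.root) if sol.converged else e0
    if abs(err) > tol:
        raise ValidationError(
            "secretion target unreachable: residual log-error "
            f"{err:.3g} at S_0 = {state['s0']:.4g} nM/h "
            f"(CSF = {state['csf']:.4g} pM vs target {target_csf} pM)"
        )
    s0 = state["s0"]
    s1 = targets.oligomer_fraction * s0
    ss, model = state["ss"], state["model"]
    isf_pM, csf_pM = _chain_levels(model, ss, geometry)
    return CalibrationResult(
        secretion_rates=np.array([s0, s1]),
        steady_state=ss,
        csf_pM=csf_pM,
        isf_pM=isf_pM,
        targets=targets,
        model=model,
    )


def _oligomer_loss_rate(model: SynapseModel, ss: CleftState) -> float:
    """Effective first-order loss of free oligomer at the baseline state."""
    sp = model.species[1]
    f, b, a = sp.receptor_on_rate, sp.receptor_off_rate, sp.internalization_rate
    return sp.cleft_efflux_rate + f * ss.R * a / (b + a)


# ---------------------------------------------------------------------------
# In-vitro uptake fitting (bath model)
# ---------------------------------------------------------------------------

UPTAKE_MODES = ("tau-hiPSC", "tau-brain-extract", "aSyn-PFF")


@dataclass
class UptakeResults:
    """Fitted uptake parameters of the reduced bath model."""

    mode: str
    params: dict[str, float]
    residuals: np.ndarray
    data: pd.DataFrame
    profile_warning: str | None = None

    @property
    def sse(self) -> float:
        return float(np.sum(self.residuals**2))

    def summary(self) -> str:
        lines = [f"Uptake fit ({self.mode})"]
        for k, v in self.params.items():
            lines.append(f"  {k:22s}: {v:.5g}")
        lines.append(f"  SSE: {self.sse:.4g}")
        if self.profile_warning:
            lines.append(f"  WARNING: {self.profile_warning}")
        return "\n".join(lines)


class UptakeModel:
    """Fit the cell-culture bath model to uptake data.

    The bath model is the cleft system with S_i = 0 and a constant
    extracellular concentration (excess-volume culture assumption): receptor
    binding, internalization and (tau modes) pinocytosis drive an
    internalized amount C(t) whose proportional readout is the measured
    signal.

    Data formats
    ------------
    ``tau-hiPSC``       : columns time_h, bath_nM, signal (time courses,
                          possibly at several bath concentrations); fits
                          (receptor_on_rate, internalization_rate,
                          pino_on_rate, pino_internalization_rate) with the
                          receptor Kd and pool sizes known.
    ``tau-brain-extract``: same columns; fits (receptor_kd,
                          internalization_rate).
    ``aSyn-PFF``        : columns dose_nM, signal (endpoint uptake after
                          ``endpoint_h`` = 1 h); fits (receptor_kd,
                          internalization_rate).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        mode: str,
        *,
        receptor_total: float = 10000.0,
        receptor_kd: float = 60.0,
        receptor_on_rate: float = 0.36,
        pino_total: float = 1000.0,
        endpoint_h: float = 1.0,
    ):
        if mode not in UPTAKE_MODES:
            raise ValidationError(f"unknown mode {mode!r}; available: {UPTAKE_MODES}")
        if len(data) < 5:
            raise ValidationError("need at least 5 uptake data points")
        self.data = data.reset_index(drop=True)
        self.mode = mode
        self.receptor_total = receptor_total
        self.receptor_kd = receptor_kd
        self.receptor_on_rate = receptor_on_rate
        self.pino_total = pino_total
        self.endpoint_h = endpoint_h

    # -- bath forward model --------------------------------------------------

    def _internalized(self, bath_nM, times, kd, f_on, a, f_pino, a_pino) -> np.ndarray:
        """C(t) for a constant bath concentration."""
        b = kd * f_on
        Rbar = self.receptor_total
        T = bath_nM

        def rhs(t, y):
            Rb, P0, C = y
            R = max(Rbar - Rb, 0.0)
            dRb = f_on * T * R - (b + a) * Rb
            dP0 = f_pino * T * (self.pino_total - P0) - a_pino * P0
            dC = a * Rb + a_pino * P0
            return [dRb, dP0, dC]

        t_end = float(np.max(times))
        sol = solve_ivp(
            rhs, (0.0, t_end), [0.0, 0.0, 0.0], t_eval=np.asarray(times, dtype=float),
            method="LSODA", rtol=1e-9, atol=1e-12,
        )
        return sol.y[2]

    def _predict(self, theta: np.ndarray) -> np.ndarray:
        if self.mode == "tau-hiPSC":
            f_on, a, f_pino, a_pino = np.exp(theta)
            kd = self.receptor_kd
        else:
            kd, a = np.exp(theta)
            f_on = self.receptor_on_rate
            f_pino = a_pino = 0.0
        out = np.empty(len(self.data))
        if self.mode == "aSyn-PFF":
            for j, dose in enumerate(self.data["dose_nM"].to_numpy()):
                out[j] = self._internalized(dose, [self.endpoint_h], kd, f_on, a, f_pino, a_pino)[-1]
        else:
            for bath, grp in self.data.groupby("bath_nM"):
                c = self._internalized(
                    bath, grp["time_h"].to_numpy(), kd, f_on, a, f_pino, a_pino
                )
                out[grp.index.to_numpy()] = c
        return out

    def fit(self, x0: dict[str, float] | None = None) -> UptakeResults:
        signal = self.data["signal"].to_numpy(dtype=float)
        if self.mode == "tau-hiPSC":
            names = ["receptor_on_rate", "internalization_rate",
                     "pino_on_rate", "pino_internalization_rate"]
            defaults = [0.1, 0.01, 1e-5, 0.1]
        else:
            names = ["receptor_kd", "internalization_rate"]
            defaults = [100.0, 0.05]
        if x0:
            defaults = [x0.get(n, d) for n, d in zip(names, defaults)]
        theta0 = np.log(defaults)

        def resid(theta):
            return self._predict(theta) - signal

        sol = least_squares(resid, theta0, method="lm", max_nfev=4000)
        params = dict(zip(names, np.exp(sol.x)))
        warning = None
        # flat-residual-surface diagnostic: profile each parameter +/- 20%
        base = self.sse_of(sol.x)
        scale = max(base, 1e-12 * float(np.sum(signal**2)) + 1e-300)
        for k, name in enumerate(names):
            bumped = sol.x.copy()
            bumped[k] += np.log(1.2)
            if self.sse_of(bumped) < scale * 1.001 and base > 0:
                warning = (
                    f"parameter {name} is weakly identified "
                    "(flat residual surface within +/-20%)"
                )
                warnings.warn(warning)
                break
        if self.mode == "tau-hiPSC":
            # share of steady-state uptake flux through pinocytosis at the
            # median bath concentration, reported for interpretation
            bath = float(np.median(self.data["bath_nM"]))
            f_on, a = params["receptor_on_rate"], params["internalization_rate"]
            b = self.receptor_kd * f_on
            occ = f_on * bath / (b + a)
            rb = self.receptor_total * occ / (1 + occ)
            fp, ap = params["pino_on_rate"], params["pino_internalization_rate"]
            p_occ = fp * bath / (fp * bath + ap)
            pino_flux = ap * self.pino_total * p_occ
            params["pinocytosis_fraction"] = pino_flux / (pino_flux + a * rb)
        return UptakeResults(
            mode=self.mode, params=params, residuals=sol.fun,
            data=self.data, profile_warning=warning,
        )

    def sse_of(self, theta: np.ndarray) -> float:
        r = self._predict(theta) - self.data["signal"].to_numpy(dtype=float)
        return float(np.sum(r**2))


def fit_uptake(uptake_data: pd.DataFrame, mode: str, **kwargs) -> UptakeResults:
    """Functional wrapper over :class:`UptakeModel`."""
    return UptakeModel(uptake_data, mode, **kwargs).fit()
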