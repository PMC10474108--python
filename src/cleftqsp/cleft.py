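"""Synaptic-cleft ODE system: secretion, receptor binding, pinocytosis,
antibody capture and neuronal internalization of tau / aSyn species.

For each species i the free cleft concentration obeys

    dT_i/dt = S_i - f_i^R T_i R + b_i^R R_i - f_i^A T_i A - k_out,i T_i

with k_out,i = ln2 / H_i the diffusion-controlled escape to the ISF.  The
receptor pool follows

    dR_i/dt = f_i^R T_i R - (b_i^R + a_i) R_i
    dR/dt   = -(sum_i f_i^R T_i) R + sum_i b_i^R R_i
              + r [ (R_bar - sum_i R_i) - R ]

and internalized protein accumulates as dC_i/dt = a_i R_i - kdeg C_i.  Tau
monomer has an additional pinocytosis route through a conserved pool of
binding sites (P + P_0 = const):

    dP/dt  = -f_0^P T_0 P + a_0^P P_0        dP_0/dt = -dP/dt
    dC_0/dt = a_0 R_0 + a_0^P P_0 - kdeg C_0

with the matching -f_0^P T_0 P loss on free monomer so protein mass balances.

Antibody in the cleft is either prescribed (fast-equilibrium mode) or a
state flow-coupled to the ISF and consumed stoichiometrically by capture:

    dA/dt = (Q/V_cleft) (A_isf(t) - A) - sum_i f_i^A T_i A

Capture is irreversible; captured protein leaves the system and is tallied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .geometry import BrainGeometry, ValidationError
from .species import Antibody, CleftState, PinocytosisPool, ProteinSpecies, ReceptorPool

LN2 = math.log(2.0)


class IntegrationError(RuntimeError):
    """Raised when the stiff cleft integration fails."""


@dataclass(frozen=True)
class SolverOptions:
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-12
    max_step: float = np.inf


class SynapseModel:
    """The cleft reaction system for a fixed parameter set.

    Parameters
    ----------
    species
        One :class:`ProteinSpecies` per simulated form (index 0 = monomer).
    receptors
        The lumped postsynaptic acceptor pool.
    pinocytosis
        Optional monomer bulk-uptake pool (tau only; ``None`` for aSyn).
    antibody
        Optional :class:`Antibody`; without it all capture terms vanish.
    geometry
        Needed only when the cleft antibody is a flow-coupled state.
    """

    def __init__(
        self,
        species: Sequence[ProteinSpecies],
        receptors: ReceptorPool,
        pinocytosis: PinocytosisPool | None = None,
        antibody: Antibody | None = None,
        geometry: BrainGeometry | None = None,
    ):
        if len(species) < 1:
            raise ValidationError("need at least one protein species")
        self.species = list(species)
        self.receptors = receptors
        self.pinocytosis = pinocytosis
        self.antibody = antibody
        self.geometry = geometry or BrainGeometry()
        n = len(self.species)
        self._S = np.array([s.secretion_rate for s in self.species])
        self._fR = np.array([s.receptor_on_rate for s in self.species])
        self._bR = np.array([s.receptor_off_rate for s in self.species])
        self._a = np.array([s.internalization_rate for s in self.species])
        self._kout = np.array([s.cleft_efflux_rate for s in self.species])
        self._kdeg = np.array([s.degradation_rate for s in self.species])
        self._kextra = np.array([s.extra_cleft_degradation for s in self.species])
        if antibody is not None:
            self._fA = antibody.capture_rates(n)
        else:
            self._fA = np.zeros(n)

    @property
    def n_species(self) -> int:
        return len(self.species)

    # -- derivative field ----------------------------------------------------

    def rhs(self, y: np.ndarray, antibody_cleft: float | None) -> np.ndarray:
        """Raw derivative of the packed state vector.

        ``antibody_cleft`` overrides the antibody state (fast-equilibrium /
        prescribed mode); pass ``None`` to use the depleting state ``y[A]``.
        """
        n = self.n_species
        st = CleftState.from_vector(y, n)
        T = np.clip(st.T, -1e-12, None)
        Rb = np.clip(st.R_bound, -1e-12, None)
        R = max(st.R, -1e-12)
        A = st.A if antibody_cleft is None else antibody_cleft

        bind = self._fR * T * R
        unbind = self._bR * Rb
        capture = self._fA * T * A
        efflux = self._kout * T

        dT = self._S - bind + unbind - capture - efflux - self._kextra * T
        dRb = bind - (self._bR + self._a) * Rb
        dR = -bind.sum() + unbind.sum() + self.receptors.recovery_rate * (
            (self.receptors.total - Rb.sum()) - R
        )
        dC = self._a * Rb - self._kdeg * st.C

        dP = dP0 = 0.0
        if self.pinocytosis is not None:
            pino_bind = self.pinocytosis.on_rate * T[0] * st.P
            pino_internal = self.pinocytosis.internalization_rate * st.P0
            dP = -pino_bind + pino_internal
            dP0 = pino_bind - pino_internal
            dT[0] -= pino_bind
            dC[0] += pino_internal

        if antibody_cleft is None:
            dA = -capture.sum()  # ISF exchange term added by the coupled driver
        else:
            dA = 0.0

        return np.concatenate([dT, [dR], dRb, dC, [dP, dP0, dA], capture, efflux])

    def derivatives(self, state: CleftState, antibody_cleft_nM: float = 0.0) -> CleftState:
        """Time derivative of a :class:`CleftState` at prescribed cleft antibody.

        Raises :class:`cleftqsp.geometry.ValidationError` for negative state
        entries (beyond the -1e-12 integrator tolerance).
        """
        if (
            np.any(state.T < -1e-12)
            or np.any(state.R_bound < -1e-12)
            or state.R < -1e-12
            or min(state.P, state.P0) < -1e-12
        ):
            raise ValidationError("state entries must be non-negative")
        if antibody_cleft_nM < 0:
            raise ValidationError("antibody concentration must be non-negative")
        dy = self.rhs(state.to_vector(), antibody_cleft_nM)
        return CleftState.from_vector(dy, self.n_species)

    # -- simulation ----------------------------------------------------------

    def simulate(
        self,
        initial: CleftState,
        t_span: tuple[float, float],
        antibody_profile: Callable[[float], float] | float | None = None,
        *,
        deplete_antibody: bool = False,
        n_points: int = 500,
        solver: SolverOptions = SolverOptions(),
        breakpoints: Sequence[float] = (),
    ) -> "CleftTrajectory":
        """Integrate the cleft system over ``t_span``.

        ``antibody_profile`` maps time to antibody concentration (nM).  In
        the default fast-equilibrium mode it prescribes the cleft antibody
        directly; with ``deplete_antibody=True`` it is interpreted as the ISF
        concentration driving a flow-coupled, capture-depleted cleft antibody
        state.  ``breakpoints`` (e.g. dose times) split the integration so
        the stiff solver never steps over a kink in the profile.
        """
        if antibody_profile is None:
            profile = lambda t: 0.0
        elif callable(antibody_profile):
            profile = antibody_profile
        else:
            const = float(antibody_profile)
            profile = lambda t: const

        n = self.n_species
        k_flow = self.geometry.Q_isf_cleft / self.geometry.V_cleft_total

        if deplete_antibody:
            def rhs(t, y):
                dy = self.rhs(y, None)
                a_idx = 3 * n + 3
                dy[a_idx] += k_flow * (profile(t) - y[a_idx])
                return dy
        else:
            def rhs(t, y):
                return self.rhs(y, profile(t))

        t0, t1 = t_span
        if t1 <= t0:
            raise ValidationError("t_span must be increasing")
        t_eval = np.linspace(t0, t1, n_points)
        edges = np.unique(
            np.concatenate([[t0, t1], np.asarray(list(breakpoints), dtype=float)])
        )
        edges = edges[(edges >= t0) & (edges <= t1)]

        y0 = initial.to_vector()
        ts, ys = [], []
        for a, b in zip(edges[:-1], edges[1:]):
            seg = t_eval[(t_eval >= a) & (t_eval <= b)]
            seg = np.unique(np.concatenate([[a], seg, [b]]))
            sol = solve_ivp(
                rhs, (a, b), y0, method=solver.method, t_eval=seg,
                rtol=solver.rtol, atol=solver.atol, max_step=solver.max_step,
            )
            if not sol.success:
                raise IntegrationError(
                    "stiff cleft integration failed on "
                    f"[{a:g}, {b:g}] h: {sol.message}"
                )
            ts.append(sol.t)
            ys.append(sol.y)
            y0 = sol.y[:, -1]
        t_all = np.concatenate(ts)
        y_all = np.concatenate(ys, axis=1)
        t_all, idx = np.unique(t_all, return_index=True)
        y_all = y_all[:, idx]
        if not deplete_antibody:
            y_all[3 * n + 3] = np.array([profile(t) for t in t_all])
        return CleftTrajectory(model=self, t=t_all, y=y_all)

    # -- steady state ----------------------------------------------------------

    def steady_state(
        self,
        *,
        horizon_h: float = 20000.0,
        residual_tol: float = 1e-10,
        initial: CleftState | None = None,
    ) -> CleftState:
        """Antibody-free steady state (baseline) of the cleft system.

        Long-horizon integration followed by a Newton polish on the
        equilibrating states (T_i, R, R_i, P, P_0); the horizon is extended
        automatically if slow modes have not settled.  Cumulative
        internalized protein C_i has no steady state when kdeg = 0 and is
        returned as 0 (with kdeg > 0 it is set to its fixed point
        a_i R_i / kdeg).  ``initial`` provides a warm start.
        """
        if np.any(self._S > 0) and np.all(self._kout + self._kextra == 0) and np.all(self._a == 0):
            raise ValidationError("no loss path: steady state requires positive loss rates")
        n = self.n_species
        P_total = self.pinocytosis.total if self.pinocytosis else 0.0
        if initial is None:
            init = CleftState(
                T=np.zeros(n), R=self.receptors.total, R_bound=np.zeros(n),
                C=np.zeros(n), P=P_total, P0=0.0, A=0.0,
            )
        else:
            init = initial.copy()
        cold = CleftState(
            T=np.zeros(n), R=self.receptors.total, R_bound=np.zeros(n),
            C=np.zeros(n), P=P_total, P0=0.0, A=0.0,
        ).to_vector()

        def integrate(y_start, horizon):
            last_err = None
            for method in ("LSODA", "BDF"):
                try:
                    traj = self.simulate(
                        CleftState.from_vector(y_start, n), (0.0, horizon),
                        antibody_profile=0.0, n_points=50,
                        solver=SolverOptions(method=method, rtol=1e-10, atol=1e-14),
                    )
                    return traj.y[:, -1]
                except IntegrationError as err:
                    last_err = err
            raise last_err

        y_end = init.to_vector()
        scale = max(float(np.max(self._S, initial=0.0)), 1.0)
        for attempt in range(3):
            try:
                y_end = integrate(y_end, horizon_h * 10**attempt)
            except IntegrationError:
                # a bad warm start can defeat the stiff solver; restart cold
                y_end = integrate(cold, horizon_h * 10**attempt)
            dy = self.rhs(y_end, 0.0)
            if float(np.max(np.abs(dy[: 2 * n + 1]))) < 1e-7 * scale:
                break

        # Newton polish on the equilibrating block
        def pack(y):
            st = CleftState.from_vector(y, n)
            return np.concatenate([st.T, [st.R], st.R_bound, [st.P]])

        def unpack(x, template):
            st = CleftState.from_vector(template.copy(), n)
            st.T = x[:n]
            st.R = x[n]
            st.R_bound = x[n + 1 : 2 * n + 1]
            st.P = x[2 * n + 1]
            st.P0 = P_total - st.P
            return st

        def residual(x):
            st = unpack(x, y_end)
            dy = self.rhs(st.to_vector(), 0.0)
            dst = CleftState.from_vector(dy, n)
            return np.concatenate([dst.T, [dst.R], dst.R_bound, [dst.P]])

        sol = root(residual, pack(y_end), method="hybr", tol=1e-13)
        x = sol.x if sol.success else pack(y_end)
        res_norm = float(np.max(np.abs(residual(x))))
        # tolerance is relative to the secretion flux scale for large systems
        residual_tol = max(residual_tol, 1e-12 * float(np.max(self._S, initial=0.0)))
        if res_norm > residual_tol:
            raise IntegrationError(
                f"steady-state residual {res_norm:.2e} nM/h above tolerance; "
                "review parameters (a loss rate may be vanishingly small)"
            )
        st = unpack(x, y_end)
        st.T = np.clip(st.T, 0.0, None)
        st.R_bound = np.clip(st.R_bound, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            C_ss = np.where(self._kdeg > 0, self._a * st.R_bound / np.where(self._kdeg > 0, self._kdeg, 1.0), 0.0)
        st.C = C_ss
        st.captured = np.zeros(n)
        st.effluxed = np.zeros(n)
        st.A = 0.0
        return st

    # -- derived quantities ----------------------------------------------------

    def uptake_rate(self, state: CleftState) -> np.ndarray:
        """Instantaneous neuronal uptake rate per species (nM/h)."""
        rate = self._a * np.asarray(state.R_bound)
        if self.pinocytosis is not None:
            rate = rate.copy()
            rate[0] += self.pinocytosis.internalization_rate * state.P0
        return rate


@dataclass
class CleftTrajectory:
    """Dense trajectory of the cleft system."""

    model: SynapseModel
    t: np.ndarray
    y: np.ndarray

    def state_at(self, idx: int) -> CleftState:
        return CleftState.from_vector(self.y[:, idx], self.model.n_species)

    @property
    def final_state(self) -> CleftState:
        return self.state_at(-1)

    def series(self, name: str, i: int = 0) -> np.ndarray:
        n = self.model.n_species
        offsets = {
            "T": i, "R": n, "R_bound": n + 1 + i, "C": 2 * n + 1 + i,
            "P": 3 * n + 1, "P0": 3 * n + 2, "A": 3 * n + 3,
            "captured": 3 * n + 4 + i, "effluxed": 4 * n + 4 + i,
        }
        return self.y[offsets[name]]

    def to_frame(self) -> pd.DataFrame:
        n = self.model.n_species
        data = {"time_h": self.t}
        for i in range(n):
            data[f"T{i}_nM"] = self.series("T", i)
        data["R_nM"] = self.series("R")
        for i in range(n):
            data[f"R{i}_nM"] = self.series("R_bound", i)
        for i in range(n):
            data[f"C{i}_nM"] = self.series("C", i)
        data["P_nM"] = self.series("P")
        data["P0_nM"] = self.series("P0")
        data["A_cleft_nM"] = self.series("A")
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def mass_balance_error(self) -> float:
        """Max relative protein mass-balance violation along the trajectory.

        Cumulative secretion must equal free + receptor-bound + pinocytosis-
        bound + internalized + captured + effluxed (+ degraded) protein at
        every output time.  Uses the integrated capture/efflux tallies; only
        valid when kdeg = 0 and extra degradation = 0.
        """
        m = self.model
        n = m.n_species
        t = self.t
        secreted = m._S[:, None] * (t - t[0])[None, :]
        init = self.state_at(0)
        total = np.zeros_like(secreted)
        for i in range(n):
            total[i] = (
                self.series("T", i) - init.T[i]
                + self.series("R_bound", i) - init.R_bound[i]
                + self.series("C", i) - init.C[i]
                + self.series("captured", i) - init.captured[i]
                + self.series("effluxed", i) - init.effluxed[i]
            )
        if m.pinocytosis is not None:
            total[0] += self.series("P0") - init.P0
        scale = np.maximum(np.abs(secreted), 1e-9)
        return float(np.max(np.abs(total - secreted) / scale))
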