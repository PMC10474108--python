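"""Domain types for the synaptic-cleft protein/receptor/antibody system.

Species are indexed i = 0 (monomer) and i >= 1 (oligomer / aggregated
species; for the alpha-synuclein antibodies the aggregated reference species
is preformed fibrils, PFF).  Concentrations are nM, time is hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import ValidationError

LN2 = math.log(2.0)

#: printed antibody capture kinetics: f_i^A = 0.001 / aff_i^A per (min * nM)
ANTIBODY_CAPTURE_CONSTANT_PER_MIN = 0.001


@dataclass(frozen=True)
class ProteinSpecies:
    """Kinetic parameters of one secreted tau / aSyn species in the cleft.

    Attributes
    ----------
    secretion_rate : nM/h (S_i), presynaptic secretion into the cleft.
    receptor_kd : nM, affinity for the lumped postsynaptic acceptor pool
        (HSPG / LRP1).
    receptor_on_rate : 1/(nM h) (f_i^R).
    internalization_rate : 1/h (a_i), absorption of receptor-bound protein.
    cleft_half_life : h (H_i), effective diffusion-controlled residence
        half-life of free protein in the cleft; the loss ln2/H_i is routed to
        the ISF pool for CSF bookkeeping.
    degradation_rate : 1/h (kdeg), intraneuronal degradation of internalized
        protein.
    extra_cleft_degradation : 1/h, optional additional extracellular
        first-order loss (off by default).
    """

    name: str
    secretion_rate: float
    receptor_kd: float
    receptor_on_rate: float = 0.36
    internalization_rate: float = 0.01
    cleft_half_life: float = 14.0
    degradation_rate: float = 0.0
    extra_cleft_degradation: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "secretion_rate", "receptor_kd", "receptor_on_rate",
            "internalization_rate", "cleft_half_life",
            "degradation_rate", "extra_cleft_degradation",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.receptor_kd <= 0 or self.cleft_half_life <= 0:
            raise ValidationError("receptor_kd and cleft_half_life must be positive")

    @property
    def receptor_off_rate(self) -> float:
        """b_i^R = Kd * f_i^R (1/h)."""
        return self.receptor_kd * self.receptor_on_rate

    @property
    def cleft_efflux_rate(self) -> float:
        """k_out,i = ln2 / H_i (1/h)."""
        return LN2 / self.cleft_half_life

    def with_(self, **kwargs) -> "ProteinSpecies":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ReceptorPool:
    """Lumped postsynaptic acceptor pool (HSPG / LRP1).

    ``total`` is the initial receptor concentration R-bar (nM; 10,000 nM
    corresponds to ~250 molecules in a synapse-sized volume), ``recovery_rate``
    r (1/h) replaces internalized receptors.
    """

    total: float = 10000.0
    recovery_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.total < 0 or self.recovery_rate < 0:
            raise ValidationError("receptor pool parameters must be non-negative")


@dataclass(frozen=True)
class PinocytosisPool:
    """Receptor-independent bulk uptake of tau monomer.

    A conserved pool of binding sites P + P_0 = total; free sites bind
    monomer at ``on_rate`` (f_0^P) and internalize at
    ``internalization_rate`` (a_0^P), which recycles the site.
    """

    total: float = 1000.0
    on_rate: float = 2e-5
    internalization_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.total < 0 or self.on_rate < 0 or self.internalization_rate < 0:
            raise ValidationError("pinocytosis parameters must be non-negative")


@dataclass(frozen=True)
class Antibody:
    """A therapeutic antibody: affinities (nM), plasma half-life (h).

    Capture is irreversible with forward rate f_i^A = 0.001 / Kd_i per
    (min nM), i.e. 0.06 / Kd_i per (h nM); Kd_mono applies to species 0 and
    Kd_oligo to all aggregated species.
    """

    name: str
    kd_mono: float
    kd_oligo: float
    half_life_h: float
    mw_kda: float = 150.0

    def __post_init__(self) -> None:
        if self.kd_mono <= 0 or self.kd_oligo <= 0:
            raise ValidationError("antibody Kd values must be positive")
        if self.half_life_h <= 0:
            raise ValidationError("antibody half-life must be positive")

    def kd(self, i: int) -> float:
        return self.kd_mono if i == 0 else self.kd_oligo

    def capture_rate(self, i: int) -> float:
        """f_i^A in 1/(h nM)."""
        return ANTIBODY_CAPTURE_CONSTANT_PER_MIN * 60.0 / self.kd(i)

    def capture_rates(self, n_species: int) -> np.ndarray:
        return np.array([self.capture_rate(i) for i in range(n_species)])

    def with_(self, **kwargs) -> "Antibody":
        return replace(self, **kwargs)


@dataclass
class CleftState:
    """State of the synaptic-cleft ODE system (all nM).

    ``captured`` and ``effluxed`` are cumulative tallies of antibody-captured
    and diffused-out protein used for mass-balance accounting; they are not
    dynamical drivers.
    """

    T: np.ndarray                 # free protein per species
    R: float                      # free receptors
    R_bound: np.ndarray           # receptor-bound protein per species
    C: np.ndarray                 # cumulative internalized protein per species
    P: float = 0.0                # free pinocytosis sites (tau only)
    P0: float = 0.0               # occupied pinocytosis sites
    A: float = 0.0                # free antibody in the cleft
    captured: np.ndarray | None = None
    effluxed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.R_bound = np.asarray(self.R_bound, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        n = len(self.T)
        if len(self.R_bound) != n or len(self.C) != n:
            raise ValidationError("T, R_bound and C must have one entry per species")
        if self.captured is None:
            self.captured = np.zeros(n)
        if self.effluxed is None:
            self.effluxed = np.zeros(n)
        self.captured = np.asarray(self.captured, dtype=float)
        self.effluxed = np.asarray(self.effluxed, dtype=float)

    @property
    def n_species(self) -> int:
        return len(self.T)

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.T, [self.R], self.R_bound, self.C, [self.P, self.P0, self.A],
             self.captured, self.effluxed]
        )

    @classmethod
    def from_vector(cls, y: np.ndarray, n_species: int) -> "CleftState":
        y = np.asarray(y, dtype=float)
        n = n_species
        T = y[:n]
        R = y[n]
        Rb = y[n + 1 : 2 * n + 1]
        C = y[2 * n + 1 : 3 * n + 1]
        P, P0, A = y[3 * n + 1 : 3 * n + 4]
        capt = y[3 * n + 4 : 4 * n + 4]
        eff = y[4 * n + 4 : 5 * n + 4]
        return cls(T=T, R=R, R_bound=Rb, C=C, P=P, P0=P0, A=A,
                   captured=capt, effluxed=eff)

    @staticmethod
    def vector_size(n_species: int) -> int:
        return 5 * n_species + 4

    def copy(self) -> "CleftState":
        return CleftState(
            T=self.T.copy(), R=self.R, R_bound=self.R_bound.copy(),
            C=self.C.copy(), P=self.P, P0=self.P0, A=self.A,
            captured=self.captured.copy(), effluxed=self.effluxed.copy(),
        )
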