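"""Preset registry: the five clinical antibodies and three disease models.

Antibody presets carry the published affinities and half-lives (half-life
ranges are simulated at their midpoint; the range is kept for bracketing
runs).  Disease presets hold the kinetic parameterization of the synaptic
cleft system; secretion rates are not stored — they are calibrated at run
time so that the steady-state free CSF monomer matches the clinical level
(see :mod:`cleftqsp.calibration`).

Rate constants that are not printed in the clinical literature
(internalization rates, effective cleft residence half-lives) were fixed by
calibrating the model against the published trial simulations and in-vitro
uptake behaviour; see docs/methods.md for the anchor set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .geometry import ValidationError
from .species import Antibody, PinocytosisPool, ProteinSpecies, ReceptorPool


@dataclass(frozen=True)
class AntibodyPreset:
    antibody: Antibody
    half_life_range_h: tuple[float, float]
    doses_mg: tuple[float, ...]
    indication: str


@dataclass(frozen=True)
class DiseaseSpec:
    """Parameterization of one disease condition (tau-AD, tau-PSP, aSyn-PD).

    ``csf_monomer_pM`` is the calibration target for steady-state free CSF
    monomer; ``oligomer_fraction`` the oligomer:monomer secretion ratio
    (for aSyn, whose two species share their kinetics, this is also the
    free-level ratio in every compartment).

    Monomer and oligomer have independent receptor kinetics: monomeric
    protein associates slowly with internalization-competent acceptor sites
    but is absorbed quickly once bound, while multivalent oligomer binds
    avidly (printed Kd) and internalizes slowly, so its uptake scales with
    receptor affinity.
    """

    name: str
    protein: str                      # "tau" or "asyn"
    protein_mw_kda: float
    csf_monomer_pM: float
    isf_monomer_range_pM: tuple[float, float]
    oligomer_fraction: float
    receptor_kd_mono: float           # nM
    receptor_kd_oligo: float          # nM
    receptor_on_rate_mono: float      # f_0^R, 1/(nM h)
    receptor_on_rate_oligo: float     # f_1^R, 1/(nM h)
    internalization_mono: float       # a_0, 1/h
    internalization_oligo: float      # a_1, 1/h
    cleft_half_life_h: float          # H, shared by both species
    receptor_total: float = 10000.0   # R-bar, nM
    receptor_recovery: float = 1.0    # r, 1/h
    degradation_rate: float = 0.0     # kdeg, 1/h
    pinocytosis: PinocytosisPool | None = None

    def __post_init__(self) -> None:
        if self.protein not in ("tau", "asyn"):
            raise ValidationError("protein must be 'tau' or 'asyn'")
        if not 0 < self.oligomer_fraction <= 1:
            raise ValidationError("oligomer_fraction must lie in (0, 1]")
        if self.csf_monomer_pM <= 0:
            raise ValidationError("csf_monomer_pM must be positive")

    def receptor_pool(self) -> ReceptorPool:
        return ReceptorPool(total=self.receptor_total, recovery_rate=self.receptor_recovery)

    def species(self, secretion_rates=(0.0, 0.0)) -> list[ProteinSpecies]:
        """Monomer + oligomer :class:`ProteinSpecies` with given secretion."""
        s0, s1 = secretion_rates
        common = dict(
            cleft_half_life=self.cleft_half_life_h,
            degradation_rate=self.degradation_rate,
        )
        return [
            ProteinSpecies(
                name=f"{self.protein}-monomer", secretion_rate=s0,
                receptor_kd=self.receptor_kd_mono,
                receptor_on_rate=self.receptor_on_rate_mono,
                internalization_rate=self.internalization_mono, **common,
            ),
            ProteinSpecies(
                name=f"{self.protein}-oligomer", secretion_rate=s1,
                receptor_kd=self.receptor_kd_oligo,
                receptor_on_rate=self.receptor_on_rate_oligo,
                internalization_rate=self.internalization_oligo, **common,
            ),
        ]

    def with_(self, **kwargs) -> "DiseaseSpec":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Antibody presets (published affinities / half-lives; ranges at midpoint)
# ---------------------------------------------------------------------------

ANTIBODIES: dict[str, AntibodyPreset] = {
    "gosuranemab": AntibodyPreset(
        Antibody("gosuranemab", kd_mono=0.1, kd_oligo=0.1, half_life_h=600.0),
        half_life_range_h=(550.0, 650.0), doses_mg=(2000.0, 4000.0), indication="tau-psp",
    ),
    "tilavonemab": AntibodyPreset(
        Antibody("tilavonemab", kd_mono=20.0, kd_oligo=20.0, half_life_h=765.0),
        half_life_range_h=(650.0, 880.0), doses_mg=(2000.0, 4000.0), indication="tau-psp",
    ),
    "semorinemab": AntibodyPreset(
        Antibody("semorinemab", kd_mono=3.8, kd_oligo=3.8, half_life_h=400.0),
        half_life_range_h=(400.0, 400.0), doses_mg=(1500.0, 4500.0, 8100.0), indication="tau-ad",
    ),
    "cinpanemab": AntibodyPreset(
        Antibody("cinpanemab", kd_mono=100.0, kd_oligo=0.1, half_life_h=700.0),
        half_life_range_h=(700.0, 700.0), doses_mg=(250.0, 1250.0, 3500.0), indication="asyn-pd",
    ),
    "prasinezumab": AntibodyPreset(
        Antibody("prasinezumab", kd_mono=20.0, kd_oligo=0.05, half_life_h=260.0),
        half_life_range_h=(260.0, 260.0), doses_mg=(1500.0, 4500.0), indication="asyn-pd",
    ),
}


# ---------------------------------------------------------------------------
# Disease presets
# ---------------------------------------------------------------------------

_TAU_COMMON = dict(
    protein="tau",
    protein_mw_kda=60.0,
    oligomer_fraction=0.01,           # 100:1 monomer:oligomer secretion
    receptor_kd_mono=60.0,            # LRP1-like full-length tau affinity
    receptor_on_rate_mono=5.1e-6,     # slow association, fast absorption
    receptor_on_rate_oligo=0.36,      # avid multivalent binding, ~1e5 /(M s)
    internalization_mono=0.5,
    internalization_oligo=3.6e-3,
    cleft_half_life_h=18000.0,
    pinocytosis=PinocytosisPool(total=1000.0, on_rate=2e-5, internalization_rate=0.1),
)

DISEASES: dict[str, DiseaseSpec] = {
    "tau-psp": DiseaseSpec(
        name="tau-psp",
        csf_monomer_pM=3.0,           # 180 pg/ml at 60 kDa; PSP CSF tau not elevated
        isf_monomer_range_pM=(3.3, 66.0),
        receptor_kd_oligo=0.3,
        **_TAU_COMMON,
    ),
    "tau-ad": DiseaseSpec(
        name="tau-ad",
        csf_monomer_pM=6.7,           # ~2x healthy-control level
        isf_monomer_range_pM=(3.3, 66.0),
        receptor_kd_oligo=40.0,
        **_TAU_COMMON,
    ),
    "asyn-pd": DiseaseSpec(
        name="asyn-pd",
        protein="asyn",
        protein_mw_kda=17.41,
        csf_monomer_pM=112.0,         # 1950 pg/ml at 17.41 kDa
        isf_monomer_range_pM=(44.0, 620.0),
        oligomer_fraction=0.275,      # PFF/aggregated pool, 25-30% of monomer
        receptor_kd_mono=800.0,
        receptor_kd_oligo=800.0,      # PFF affinity for the postsynaptic receptor
        receptor_on_rate_mono=0.36,
        receptor_on_rate_oligo=0.36,
        internalization_mono=0.02,
        internalization_oligo=0.02,
        cleft_half_life_h=13.7,
        pinocytosis=None,
    ),
}


def get_antibody(name: str) -> Antibody:
    try:
        return ANTIBODIES[name].antibody
    except KeyError:
        raise ValidationError(
            f"unknown antibody preset {name!r}; available: {sorted(ANTIBODIES)}"
        ) from None


def get_disease(name: str) -> DiseaseSpec:
    try:
        return DISEASES[name]
    except KeyError:
        raise ValidationError(
            f"unknown disease preset {name!r}; available: {sorted(DISEASES)}"
        ) from None
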