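"""Brain compartment geometry for the antibody distribution model.

The model tracks four extracellular compartments relevant to antibody-mediated
capture of secreted tau / alpha-synuclein: plasma, cerebrospinal fluid (CSF),
brain interstitial fluid (ISF), and the lumped synaptic cleft.  The cleft is
tiny (~1 mL total across ~1e14 synapses) but is where secretion, receptor
binding and neuronal uptake happen, so its volume and its flow coupling to
the ISF control how much antibody is available at the site of action.

Default volumes: the neuronal compartment is 58% of brain volume (0.76 L),
ISF ~20% (0.26 L); with a 40 nm cleft width and ~0.1-1 um^2 synaptic
apposition area each synapse encloses 4e-18..4e-17 L, and 1e11 neurons with
~1000 synapses each give a total cleft volume of order 0.001 L.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

AVOGADRO = 6.02214076e23


class ValidationError(ValueError):
    """Raised when a model input violates a structural constraint."""


@dataclass(frozen=True)
class BrainGeometry:
    """Fixed volumes (L) and flows (L/h) of the brain compartments.

    ``Q_isf_cleft`` is the antibody exchange flow between ISF and the lumped
    synaptic cleft; ``Q_isf_csf`` the bulk ISF drainage into CSF carrying
    secreted protein; ``Q_csf_clear`` the CSF turnover clearing protein (and
    matching CSF production, ~0.35 mL/min).
    """

    V_csf: float = 0.15
    V_isf: float = 0.26
    V_neuron: float = 0.76
    V_cleft_total: float = 0.001
    V_cleft_per_synapse: float = 1e-17
    n_neurons: float = 1e11
    synapses_per_neuron: float = 1000.0
    cleft_width_nm: float = 40.0
    Q_isf_cleft: float = 0.001
    Q_isf_csf: float = 0.0075
    Q_csf_clear: float = 0.021

    def __post_init__(self) -> None:
        for name in (
            "V_csf", "V_isf", "V_neuron", "V_cleft_total",
            "V_cleft_per_synapse", "n_neurons", "synapses_per_neuron",
            "cleft_width_nm", "Q_isf_cleft", "Q_isf_csf", "Q_csf_clear",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        derived = self.n_neurons * self.synapses_per_neuron * self.V_cleft_per_synapse
        ratio = derived / self.V_cleft_total
        # order-of-magnitude bookkeeping: per-synapse x count must agree with
        # the lumped total within a factor of two
        if not (0.5 <= ratio <= 2.0):
            raise ValidationError(
                "inconsistent cleft bookkeeping: n_neurons * synapses_per_neuron"
                f" * V_cleft_per_synapse = {derived:g} L vs V_cleft_total = "
                f"{self.V_cleft_total:g} L (off by more than 2x)"
            )

    @property
    def n_synapses(self) -> float:
        return self.n_neurons * self.synapses_per_neuron

    def with_(self, **kwargs) -> "BrainGeometry":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def molecules_per_synapse(
    concentration_nM: float,
    geometry: BrainGeometry | None = None,
    *,
    volume_per_synapse: float | None = None,
) -> float:
    """Convert a cleft concentration (nM) to a molecule count per synapse.

    count = C * N_A * V_synapse, with C in mol/L.  Note that at the default
    1e-17 L per synapse even a 1 nM solute averages well below one molecule
    per cleft (~6e-3), so per-synapse counts of order one correspond to
    concentrations in the hundreds-of-nM range.
    """
    if concentration_nM < 0:
        raise ValidationError("concentration must be non-negative")
    if volume_per_synapse is None:
        volume_per_synapse = (geometry or BrainGeometry()).V_cleft_per_synapse
    if volume_per_synapse <= 0:
        raise ValidationError("volume_per_synapse must be strictly positive")
    return concentration_nM * 1e-9 * AVOGADRO * volume_per_synapse
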