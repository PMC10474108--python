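import warnings

import numpy as np
import pytest

from cleftqsp import (
    ProteinSpecies,
    ReceptorPool,
    SynapseModel,
    TrialSpec,
    calibrate_secretion,
    get_antibody,
    get_disease,
)
from cleftqsp.reproduce import q4w_regimen
from cleftqsp.trials import run_trial

warnings.filterwarnings("ignore", message="lsoda")


@pytest.fixture(scope="session")
def asyn_calibration():
    return calibrate_secretion(get_disease("asyn-pd"))


@pytest.fixture(scope="session")
def psp_calibration():
    return calibrate_secretion(get_disease("tau-psp"))


@pytest.fixture(scope="session")
def cinpanemab_trials():
    """Cinpanemab phase-2 dose ladder (full 52-week runs), shared by tests."""
    from cleftqsp.reproduce import _trial

    return {dose: _trial("cinpanemab", "asyn-pd", dose) for dose in (250.0, 1250.0, 3500.0)}


@pytest.fixture(scope="session")
def gosuranemab_psp_trial():
    from cleftqsp.reproduce import _trial

    return _trial("gosuranemab", "tau-psp", 4000.0)


def short_trial(antibody: str, disease: str, dose_mg: float, weeks: float = 12.0,
                n_points: int = 250, **kwargs):
    """A reduced-duration trial for property tests (3 Q4W doses)."""
    spec = TrialSpec(
        antibody=get_antibody(antibody), disease=get_disease(disease),
        regimen=q4w_regimen(dose_mg, weeks), **kwargs,
    )
    return run_trial(spec, n_points=n_points)


def single_species_model(S=1.0, H=np.log(2.0), f_A=None, antibody=None):
    """One species, no receptors, no pinocytosis: a linear birth-death system."""
    sp = ProteinSpecies(
        name="probe", secretion_rate=S, receptor_kd=1.0, receptor_on_rate=0.0,
        internalization_rate=0.0, cleft_half_life=H,
    )
    return SynapseModel([sp], ReceptorPool(total=0.0, recovery_rate=0.0),
                        antibody=antibody)
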