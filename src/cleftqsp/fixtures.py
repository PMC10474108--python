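"""Synthetic calibration datasets (plasma PK and in-vitro uptake surrogates).

The clinical calibration inputs of the model — phase-1 plasma
concentration-time profiles and fluorescent uptake assays in neuronal
cultures — are published as figures, not machine-readable tables.  This
module generates synthetic datasets with the same structure from known
("truth") parameters, so that every fitting routine in the package can be
exercised as a parameter-recovery problem.  All outputs are deterministic
given the seed, and every dataset carries a sidecar dict of the generating
truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import UptakeModel
from .geometry import ValidationError
from .pbpk import DoseRegimen, PlasmaPKParams


@dataclass
class FixtureSet:
    """A named synthetic dataset plus the parameters that generated it."""

    scenario: str
    frames: dict[str, pd.DataFrame]
    truth: dict

    def write(self, out_dir) -> list[Path]:
        """Write CSVs plus a sidecar JSON of the generating truth."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, frame in self.frames.items():
            p = out / f"{self.scenario}-{name}.csv"
            frame.to_csv(p, index=False)
            paths.append(p)
        sidecar = out / f"{self.scenario}-truth.json"
        sidecar.write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        paths.append(sidecar)
        return paths


SCENARIOS = (
    "plasma-pk",
    "gosuranemab-phase1",
    "tau-hipsc-uptake",
    "tau-brain-extract-pair",
    "asyn-pff-uptake",
)


def _noisy(rng: np.random.Generator, values: np.ndarray, noise_level: float) -> np.ndarray:
    """Multiplicative lognormal noise with geometric sd ``noise_level``."""
    if noise_level == 0:
        return values.copy()
    sigma = np.log1p(noise_level)
    return values * rng.lognormal(mean=0.0, sigma=sigma, size=values.shape)


def generate_fixtures(
    scenario: str,
    noise_level: float = 0.0,
    seed: int = 0,
    out_dir=None,
    **kwargs,
) -> FixtureSet:
    """Generate a named synthetic dataset.

    Scenarios
    ---------
    ``plasma-pk``
        Single-dose biexponential plasma profile; kwargs ``half_life_h``
        (default 700), ``dose_mg`` (default 2100).
    ``gosuranemab-phase1``
        Plasma profiles for the phase-1 single-dose panel (mg/kg doses
        including 3 mg/kg, 70 kg body weight).
    ``tau-hipsc-uptake``
        Time courses of internalized tau signal at three bath
        concentrations, receptor + pinocytosis truth.
    ``tau-brain-extract-pair``
        Endpoint uptake time courses for AD- and PSP-derived material whose
        receptor affinities differ exactly 120-fold.
    ``asyn-pff-uptake``
        1-h endpoint uptake versus applied PFF concentration, receptor
        Kd truth 800 nM.
    """
    if scenario not in SCENARIOS:
        raise ValidationError(
            f"unknown scenario {scenario!r}; available scenarios: {SCENARIOS}"
        )
    rng = np.random.default_rng(seed)
    if scenario == "plasma-pk":
        return _plasma_pk(rng, noise_level, **kwargs, scenario=scenario, out_dir=out_dir)
    if scenario == "gosuranemab-phase1":
        return _phase1_panel(rng, noise_level, scenario=scenario, out_dir=out_dir)
    if scenario == "tau-hipsc-uptake":
        return _tau_hipsc(rng, noise_level, scenario=scenario, out_dir=out_dir)
    if scenario == "tau-brain-extract-pair":
        return _brain_extract_pair(rng, noise_level, scenario=scenario, out_dir=out_dir)
    return _asyn_pff(rng, noise_level, scenario=scenario, out_dir=out_dir)


def _finalize(scenario, frames, truth, out_dir) -> FixtureSet:
    fs = FixtureSet(scenario=scenario, frames=frames, truth=truth)
    if out_dir is not None:
        fs.write(out_dir)
    return fs


def _plasma_pk(rng, noise_level, *, half_life_h=700.0, dose_mg=2100.0,
               central_volume_l=3.1, scenario, out_dir):
    pk = PlasmaPKParams(half_life_h=half_life_h, central_volume_l=central_volume_l)
    regimen = DoseRegimen(dose_mg=dose_mg, n_doses=1, interval_h=24.0,
                          trial_duration_weeks=3 * half_life_h / (7 * 24))
    t = np.array([1, 6, 24, 72, 168, 336, 504, 672, 1008, 1344, 1680, 2016], dtype=float)
    t = t[t <= regimen.duration_h]
    conc = pk.concentration(t, regimen)
    frame = pd.DataFrame({"time_h": t, "conc_nM": _noisy(rng, conc, noise_level)})
    truth = {
        "half_life_h": half_life_h,
        "central_volume_l": central_volume_l,
        "distribution_half_life_h": pk.distribution_half_life_h,
        "distribution_fraction": pk.distribution_fraction,
        "dose_mg": dose_mg,
        "noise_level": noise_level,
    }
    return _finalize(scenario, {"plasma": frame}, truth, out_dir)


def _phase1_panel(rng, noise_level, *, scenario, out_dir):
    doses_mg_kg = (1.0, 3.0, 10.0, 30.0)
    pk = PlasmaPKParams(half_life_h=600.0)
    t = np.array([1, 24, 72, 168, 336, 672, 1008, 1344, 2016], dtype=float)
    frames = {}
    for d in doses_mg_kg:
        regimen = DoseRegimen(dose_mg_per_kg=d, n_doses=1, interval_h=672.0,
                              trial_duration_weeks=13.0)
        conc = pk.concentration(t, regimen)
        frames[f"{d:g}mgkg"] = pd.DataFrame(
            {"time_h": t, "conc_nM": _noisy(rng, conc, noise_level)}
        )
    truth = {
        "half_life_h": 600.0,
        "doses_mg_kg": list(doses_mg_kg),
        "body_weight_kg": 70.0,
        "noise_level": noise_level,
    }
    return _finalize(scenario, frames, truth, out_dir)


_TAU_HIPSC_TRUTH = {
    "receptor_on_rate": 0.36,
    "internalization_rate": 4e-3,
    "pino_on_rate": 2e-5,
    "pino_internalization_rate": 0.1,
    "receptor_kd": 60.0,
    "receptor_total": 10000.0,
    "pino_total": 1000.0,
}


def _bath_curve(params, bath_nM, times, *, receptor_total, pino_total, receptor_kd):
    model = UptakeModel(
        pd.DataFrame({"time_h": times, "bath_nM": bath_nM, "signal": np.zeros(len(times))}),
        "tau-hiPSC",
        receptor_total=receptor_total, receptor_kd=receptor_kd, pino_total=pino_total,
    )
    return model._internalized(
        bath_nM, times,
        receptor_kd, params["receptor_on_rate"], params["internalization_rate"],
        params.get("pino_on_rate", 0.0), params.get("pino_internalization_rate", 0.0),
    )


def _tau_hipsc(rng, noise_level, *, scenario, out_dir):
    truth = dict(_TAU_HIPSC_TRUTH)
    times = np.array([0.5, 1, 2, 4, 8, 16, 24], dtype=float)
    rows = []
    for bath in (20.0, 100.0, 500.0):
        c = _bath_curve(truth, bath, times, receptor_total=truth["receptor_total"],
                        pino_total=truth["pino_total"], receptor_kd=truth["receptor_kd"])
        rows.append(pd.DataFrame({
            "time_h": times, "bath_nM": bath, "signal": _noisy(rng, c, noise_level)
        }))
    frame = pd.concat(rows, ignore_index=True)
    truth["noise_level"] = noise_level
    return _finalize(scenario, {"uptake": frame}, truth, out_dir)


def _brain_extract_pair(rng, noise_level, *, scenario, out_dir):
    # AD vs PSP extract uptake generated at exactly 120-fold affinity ratio
    truth = {
        "receptor_kd_ad": 40.0,
        "receptor_kd_psp": 40.0 / 120.0,
        "internalization_rate": 4e-3,
        "receptor_on_rate": 0.36,
        "receptor_total": 10000.0,
        "affinity_ratio": 120.0,
        "noise_level": noise_level,
    }
    times = np.array([0.5, 1, 2, 4, 8, 16, 24], dtype=float)
    frames = {}
    for label, kd in (("ad", truth["receptor_kd_ad"]), ("psp", truth["receptor_kd_psp"])):
        rows = []
        for bath in (5.0, 25.0, 125.0):
            params = {"receptor_on_rate": truth["receptor_on_rate"],
                      "internalization_rate": truth["internalization_rate"]}
            c = _bath_curve(params, bath, times,
                            receptor_total=truth["receptor_total"],
                            pino_total=0.0, receptor_kd=kd)
            rows.append(pd.DataFrame({
                "time_h": times, "bath_nM": bath, "signal": _noisy(rng, c, noise_level)
            }))
        frames[label] = pd.concat(rows, ignore_index=True)
    return _finalize(scenario, frames, truth, out_dir)


def _asyn_pff(rng, noise_level, *, scenario, out_dir):
    truth = {
        "receptor_kd": 800.0,
        "internalization_rate": 0.02,
        "receptor_on_rate": 0.36,
        "receptor_total": 10000.0,
        "endpoint_h": 1.0,
        "noise_level": noise_level,
    }
    doses = np.array([25, 50, 100, 200, 400, 800, 1600, 3200, 6400], dtype=float)
    model = UptakeModel(
        pd.DataFrame({"dose_nM": doses, "signal": np.zeros(len(doses))}),
        "aSyn-PFF", receptor_total=truth["receptor_total"],
        receptor_on_rate=truth["receptor_on_rate"],
    )
    signal = np.array([
        model._internalized(d, [truth["endpoint_h"]], truth["receptor_kd"],
                            truth["receptor_on_rate"], truth["internalization_rate"],
                            0.0, 0.0)[-1]
        for d in doses
    ])
    frame = pd.DataFrame({"dose_nM": doses, "signal": _noisy(rng, signal, noise_level)})
    return _finalize(scenario, {"uptake": frame}, truth, out_dir)
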