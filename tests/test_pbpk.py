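import numpy as np
import pytest

from cleftqsp import (
    BrainGeometry,
    BrainTransferParams,
    DoseRegimen,
    FittingError,
    PlasmaPKModel,
    PlasmaPKParams,
    ValidationError,
    fit_plasma_pk,
    mg_to_nmol,
    simulate_antibody_exposure,
)
from cleftqsp.fixtures import generate_fixtures


class TestDoseRegimen:
    def test_flat_dose_conversion(self):
        assert mg_to_nmol(150.0) == pytest.approx(1000.0)  # 150 mg of a 150 kDa IgG

    def test_mg_per_kg_uses_70_kg(self):
        r = DoseRegimen(dose_mg_per_kg=50.0, n_doses=1)
        assert r.flat_dose_mg == pytest.approx(3500.0)

    def test_exactly_one_dose_spec_required(self):
        with pytest.raises(ValidationError):
            DoseRegimen(dose_mg=100.0, dose_mg_per_kg=2.0)
        with pytest.raises(ValidationError):
            DoseRegimen()

    def test_negative_dose_rejected(self):
        with pytest.raises(ValidationError):
            DoseRegimen(dose_mg=-5.0)

    def test_regimen_must_fit_trial_duration(self):
        with pytest.raises(ValidationError):
            DoseRegimen(dose_mg=10.0, n_doses=20, interval_h=672.0,
                        trial_duration_weeks=12.0)


class TestPlasmaKinetics:
    def test_superposition_over_doses(self):
        """An n-dose profile equals the sum of time-shifted single doses."""
        pk = PlasmaPKParams(half_life_h=600.0)
        multi = DoseRegimen(dose_mg=1000.0, n_doses=3, interval_h=672.0,
                            trial_duration_weeks=16.0)
        t = np.linspace(0, multi.duration_h, 400)
        total = pk.concentration(t, multi)
        manual = np.zeros_like(t)
        for t0 in multi.dose_times:
            manual += multi.dose_nmol * pk.unit_impulse(t - t0)
        np.testing.assert_allclose(total, manual, rtol=1e-12)

    def test_dose_linearity_of_auc(self):
        pk = PlasmaPKParams(half_life_h=400.0)
        r1 = DoseRegimen(dose_mg=500.0, n_doses=2, interval_h=672.0,
                         trial_duration_weeks=12.0)
        r2 = r1.with_dose_mg(1000.0)
        t = np.linspace(0, r1.duration_h, 2000)
        auc1 = np.trapezoid(pk.concentration(t, r1), t)
        auc2 = np.trapezoid(pk.concentration(t, r2), t)
        assert auc2 == pytest.approx(2 * auc1, rel=1e-12)

    def test_trough_concentration_monotone_in_dose_and_half_life(self):
        trough_t = 672.0 * np.arange(1, 6) - 1.0
        base = DoseRegimen(dose_mg=1000.0, n_doses=6, interval_h=672.0,
                           trial_duration_weeks=26.0)
        troughs = {}
        for hl in (300.0, 600.0, 900.0):
            pk = PlasmaPKParams(half_life_h=hl)
            troughs[hl] = pk.concentration(trough_t, base)
        assert np.all(troughs[600.0] > troughs[300.0])
        assert np.all(troughs[900.0] > troughs[600.0])
        pk = PlasmaPKParams(half_life_h=600.0)
        low = pk.concentration(trough_t, base)
        high = pk.concentration(trough_t, base.with_dose_mg(2000.0))
        assert np.all(high > low)


class TestPlasmaFit:
    def test_noiseless_round_trip_recovers_half_life(self):
        fs = generate_fixtures("plasma-pk", half_life_h=700.0, dose_mg=2100.0)
        regimen = DoseRegimen(dose_mg=2100.0, n_doses=1, interval_h=24.0,
                              trial_duration_weeks=3 * 700 / (7 * 24))
        res = PlasmaPKModel.from_dataframe(fs.frames["plasma"], regimen).fit()
        assert abs(res.half_life_h - 700.0) < 1.0
        assert "terminal half-life" in res.summary()

    def test_noisy_fit_recovers_short_half_life_within_15pct(self):
        fs = generate_fixtures("plasma-pk", half_life_h=260.0, dose_mg=2100.0,
                               noise_level=0.1, seed=1)
        regimen = DoseRegimen(dose_mg=2100.0, n_doses=1, interval_h=24.0,
                              trial_duration_weeks=3 * 260 / (7 * 24))
        res = fit_plasma_pk(fs.frames["plasma"].to_numpy(), regimen)
        assert res.half_life_h == pytest.approx(260.0, rel=0.15)

    def test_preset_half_lives_lie_in_published_ranges(self):
        from cleftqsp.presets import ANTIBODIES

        assert ANTIBODIES["prasinezumab"].antibody.half_life_h == 260.0
        lo, hi = ANTIBODIES["tilavonemab"].half_life_range_h
        assert (lo, hi) == (650.0, 880.0)
        assert lo <= ANTIBODIES["tilavonemab"].antibody.half_life_h <= hi

    def test_too_few_points_raises_fitting_error(self):
        regimen = DoseRegimen(dose_mg=100.0, n_doses=1)
        with pytest.raises(FittingError):
            PlasmaPKModel([(1.0, 5.0), (2.0, 4.0), (3.0, 3.0)], regimen)

    def test_non_monotone_times_rejected(self):
        regimen = DoseRegimen(dose_mg=100.0, n_doses=1)
        with pytest.raises(ValidationError):
            PlasmaPKModel([(1.0, 5.0), (3.0, 4.0), (2.0, 3.0), (4.0, 2.0)], regimen)


class TestExposureSimulation:
    def test_zero_dose_is_identically_zero(self):
        res = simulate_antibody_exposure(
            PlasmaPKParams(half_life_h=600.0), BrainTransferParams(),
            BrainGeometry(), DoseRegimen(dose_mg=0.0, n_doses=1,
                                         trial_duration_weeks=8.0),
        )
        for arr in (res.plasma_nM, res.csf_nM, res.isf_nM, res.cleft_nM):
            assert np.all(arr == 0.0)

    def test_csf_exposure_ratio_in_published_window(self):
        """Steady-state trough CSF/plasma must lie in 0.1-0.4% of plasma."""
        regimen = DoseRegimen(dose_mg=2000.0, n_doses=13, interval_h=672.0,
                              trial_duration_weeks=52.0)
        res = simulate_antibody_exposure(
            PlasmaPKParams(half_life_h=600.0), BrainTransferParams(),
            BrainGeometry(), regimen,
        )
        # exposure ratio over the last full dosing interval (AUC based)
        last = res.time_h >= 12 * 672.0
        t = res.time_h[last]
        auc_plasma = np.trapezoid(res.plasma_nM[last], t)
        ratio = np.trapezoid(res.csf_nM[last], t) / auc_plasma
        assert 0.001 < ratio < 0.004
        ratio_isf = np.trapezoid(res.isf_nM[last], t) / auc_plasma
        assert 0.0007 < ratio_isf < 0.003

    def test_cleft_equilibrates_with_isf_at_flow_rate(self):
        """Uncoupled cleft (no protein binding) converges to a constant ISF
        level within 1% after 5 V/Q hours: two-compartment equilibration."""
        from cleftqsp import CleftState, SynapseModel, ProteinSpecies, ReceptorPool

        geometry = BrainGeometry(Q_isf_cleft=0.01)
        inert = ProteinSpecies("inert", secretion_rate=0.0, receptor_kd=1.0,
                               receptor_on_rate=0.0, internalization_rate=0.0,
                               cleft_half_life=10.0)
        m = SynapseModel([inert], ReceptorPool(0.0, 0.0), geometry=geometry)
        a_isf = 5.0
        init = CleftState(T=[0.0], R=0.0, R_bound=[0.0], C=[0.0], A=0.0)
        t_eq = 5 * geometry.V_cleft_total / geometry.Q_isf_cleft
        traj = m.simulate(init, (0.0, 2 * t_eq), antibody_profile=a_isf,
                          deplete_antibody=True, n_points=200)
        a = traj.series("A")
        late = traj.t >= t_eq
        assert np.all(np.abs(a[late] / a_isf - 1.0) < 0.01)
        # matches the closed form 1 - exp(-Q t / V) along the way
        k = geometry.Q_isf_cleft / geometry.V_cleft_total
        np.testing.assert_allclose(a, a_isf * (1 - np.exp(-k * traj.t)),
                                   rtol=1e-5, atol=1e-8)

    def test_cleft_never_exceeds_isf_history(self):
        """Without sources the cleft stays below the running ISF maximum."""
        res = simulate_antibody_exposure(
            PlasmaPKParams(half_life_h=600.0), BrainTransferParams(),
            BrainGeometry(), DoseRegimen(dose_mg=2000.0, n_doses=2,
                                         interval_h=672.0,
                                         trial_duration_weeks=12.0),
        )
        running_max = np.maximum.accumulate(res.isf_nM)
        assert np.all(res.cleft_nM <= running_max * (1 + 1e-9) + 1e-15)

    def test_transfer_ratio_windows_enforced(self):
        with pytest.raises(ValidationError):
            BrainTransferParams(csf_plasma_ratio=0.01)
        with pytest.raises(ValidationError):
            BrainTransferParams(csf_plasma_ratio=0.001, isf_plasma_ratio=0.002)

    def test_microglia_sink_lowers_effective_isf_ratio(self):
        clean = BrainTransferParams()
        sink = BrainTransferParams(microglia_sink_rate=0.05)
        assert sink.effective_isf_ratio < clean.effective_isf_ratio
        assert clean.effective_isf_ratio == pytest.approx(clean.isf_plasma_ratio)
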