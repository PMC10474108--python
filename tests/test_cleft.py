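import math

import numpy as np
import pytest

from cleftqsp import (
    Antibody,
    CleftState,
    PinocytosisPool,
    ProteinSpecies,
    ReceptorPool,
    SolverOptions,
    SynapseModel,
    ValidationError,
)
from conftest import single_species_model

LN2 = math.log(2.0)


def two_species_model(antibody=None, kdeg=0.0):
    species = [
        ProteinSpecies("mono", secretion_rate=10.0, receptor_kd=60.0,
                       receptor_on_rate=1e-4, internalization_rate=0.5,
                       cleft_half_life=50.0, degradation_rate=kdeg),
        ProteinSpecies("oligo", secretion_rate=0.1, receptor_kd=0.5,
                       receptor_on_rate=0.36, internalization_rate=0.01,
                       cleft_half_life=50.0, degradation_rate=kdeg),
    ]
    pino = PinocytosisPool(total=100.0, on_rate=1e-4, internalization_rate=0.1)
    return SynapseModel(species, ReceptorPool(total=1000.0, recovery_rate=1.0),
                        pinocytosis=pino, antibody=antibody)


class TestDerivatives:
    def test_zero_state_zero_secretion_gives_zero_derivative(self):
        m = single_species_model(S=0.0)
        st = CleftState(T=[0.0], R=0.0, R_bound=[0.0], C=[0.0])
        d = m.derivatives(st)
        assert np.all(d.to_vector() == 0.0)

    def test_zero_antibody_equals_no_antibody_terms(self):
        ab = Antibody("probe", kd_mono=0.1, kd_oligo=0.1, half_life_h=500.0)
        with_ab = two_species_model(antibody=ab)
        without = two_species_model(antibody=None)
        st = CleftState(T=[5.0, 0.2], R=800.0, R_bound=[100.0, 100.0],
                        C=[1.0, 1.0], P=90.0, P0=10.0, A=0.0)
        d1 = with_ab.derivatives(st, antibody_cleft_nM=0.0)
        d2 = without.derivatives(st, antibody_cleft_nM=0.0)
        np.testing.assert_allclose(d1.to_vector(), d2.to_vector(), rtol=0, atol=0)

    def test_negative_state_rejected(self):
        m = two_species_model()
        st = CleftState(T=[-1.0, 0.0], R=0.0, R_bound=[0.0, 0.0], C=[0.0, 0.0])
        with pytest.raises(ValidationError):
            m.derivatives(st)

    def test_capture_rate_constant_matches_printed_convention(self):
        """f_i^A * Kd_i = 0.001 per (min nM) exactly."""
        ab = Antibody("probe", kd_mono=3.8, kd_oligo=0.05, half_life_h=400.0)
        for i in (0, 1):
            assert ab.capture_rate(i) / 60.0 * ab.kd(i) == pytest.approx(0.001, rel=1e-12)


class TestClosedForms:
    def test_steady_state_is_secretion_times_residence(self):
        """One species, first-order loss only: T_ss = S H / ln 2."""
        m = single_species_model(S=1.0, H=LN2)
        ss = m.steady_state()
        assert ss.T[0] == pytest.approx(1.0, rel=1e-9)
        m2 = single_species_model(S=3.0, H=7.0)
        assert m2.steady_state().T[0] == pytest.approx(3.0 * 7.0 / LN2, rel=1e-9)

    def test_linear_relaxation_matches_analytic_solution(self):
        """Brute-force oracle: 1 species, no receptors -> closed-form ODE."""
        S, H = 2.0, 5.0
        k = LN2 / H
        m = single_species_model(S=S, H=H)
        init = CleftState(T=[0.0], R=0.0, R_bound=[0.0], C=[0.0])
        traj = m.simulate(init, (0.0, 40.0), n_points=200)
        analytic = S / k * (1 - np.exp(-k * traj.t))
        np.testing.assert_allclose(traj.series("T", 0), analytic, rtol=1e-6, atol=1e-9)

    def test_saturating_antibody_depletes_to_competition_balance(self):
        """Constant antibody: T -> S / (f_A A + k_out) within 1%."""
        ab = Antibody("strong", kd_mono=0.1, kd_oligo=0.1, half_life_h=500.0)
        S, H, A = 1.0, 10.0, 50.0
        m = single_species_model(S=S, H=H, antibody=ab)
        init = CleftState(T=[S * H / LN2], R=0.0, R_bound=[0.0], C=[0.0])
        traj = m.simulate(init, (0.0, 5.0), antibody_profile=A, n_points=100)
        expected = S / (ab.capture_rate(0) * A + LN2 / H)
        assert traj.final_state.T[0] == pytest.approx(expected, rel=0.01)

    def test_receptor_pool_recovers_exponentially(self):
        """With all binding rates zero, R relaxes to R_bar - sum R_i at rate r."""
        r = 0.7
        sp = ProteinSpecies("inert", secretion_rate=0.0, receptor_kd=1.0,
                            receptor_on_rate=0.0, internalization_rate=0.0,
                            cleft_half_life=10.0)
        m = SynapseModel([sp], ReceptorPool(total=100.0, recovery_rate=r))
        init = CleftState(T=[0.0], R=10.0, R_bound=[30.0], C=[0.0])
        traj = m.simulate(init, (0.0, 12.0), n_points=100)
        target = 100.0 - 30.0
        analytic = target - (target - 10.0) * np.exp(-r * traj.t)
        np.testing.assert_allclose(traj.series("R"), analytic, rtol=1e-7)


class TestTrajectoryInvariants:
    def test_pinocytosis_pool_is_conserved(self):
        m = two_species_model()
        init = CleftState(T=[1.0, 0.1], R=1000.0, R_bound=[0.0, 0.0],
                          C=[0.0, 0.0], P=100.0, P0=0.0)
        traj = m.simulate(init, (0.0, 500.0), n_points=200)
        total = traj.series("P") + traj.series("P0")
        np.testing.assert_allclose(total, 100.0, rtol=5e-13)

    def test_protein_mass_balance_closes(self):
        """Secretion = free + bound + internalized + captured + effluxed."""
        ab = Antibody("probe", kd_mono=1.0, kd_oligo=0.1, half_life_h=500.0)
        m = two_species_model(antibody=ab)
        init = CleftState(T=[0.0, 0.0], R=1000.0, R_bound=[0.0, 0.0],
                          C=[0.0, 0.0], P=100.0, P0=0.0)
        traj = m.simulate(init, (0.0, 300.0), antibody_profile=2.0, n_points=150)
        assert traj.mass_balance_error() < 1e-6

    def test_internalized_is_non_decreasing_without_degradation(self):
        m = two_species_model()
        init = CleftState(T=[0.0, 0.0], R=1000.0, R_bound=[0.0, 0.0],
                          C=[0.0, 0.0], P=100.0, P0=0.0)
        traj = m.simulate(init, (0.0, 300.0), n_points=150)
        for i in (0, 1):
            assert np.all(np.diff(traj.series("C", i)) >= -1e-10)

    def test_more_antibody_never_raises_free_or_internalized_protein(self):
        ab = Antibody("probe", kd_mono=0.5, kd_oligo=0.05, half_life_h=500.0)
        m = two_species_model(antibody=ab)
        ss = m.steady_state()
        prev_T, prev_C = None, None
        for mult in (0.0, 0.5, 2.0, 8.0):
            traj = m.simulate(ss, (0.0, 200.0), antibody_profile=mult * 1.0,
                              n_points=120)
            T1 = traj.series("T", 1)
            C1 = traj.series("C", 1)
            if prev_T is not None:
                assert np.all(T1 <= prev_T * (1 + 1e-8) + 1e-12)
                assert np.all(C1 <= prev_C * (1 + 1e-8) + 1e-12)
            prev_T, prev_C = T1, C1


class TestSteadyState:
    def test_zero_secretion_steady_state_is_protein_free(self):
        m = two_species_model()
        sp0 = [s.with_(secretion_rate=0.0) for s in m.species]
        m0 = SynapseModel(sp0, m.receptors, pinocytosis=m.pinocytosis)
        ss = m0.steady_state()
        assert np.allclose(ss.T, 0.0, atol=1e-12)
        assert np.allclose(ss.R_bound, 0.0, atol=1e-12)
        assert ss.R == pytest.approx(m.receptors.total, rel=1e-9)

    def test_steady_state_is_a_fixed_point_over_500_h(self):
        m = two_species_model()
        ss = m.steady_state()
        traj = m.simulate(ss, (0.0, 500.0), n_points=60)
        for name, i in (("T", 0), ("T", 1), ("R", 0), ("P", 0)):
            series = traj.series(name, i)
            assert np.max(np.abs(series / series[0] - 1)) < 1e-4

    def test_no_loss_path_is_rejected(self):
        sp = ProteinSpecies("stuck", secretion_rate=1.0, receptor_kd=1.0,
                            receptor_on_rate=0.0, internalization_rate=0.0,
                            cleft_half_life=np.inf)
        with pytest.raises((ValidationError, ValueError)):
            SynapseModel([sp], ReceptorPool(0.0, 0.0)).steady_state()

    def test_tightening_solver_tolerance_leaves_endpoint_unchanged(self):
        m = two_species_model()
        init = CleftState(T=[0.0, 0.0], R=1000.0, R_bound=[0.0, 0.0],
                          C=[0.0, 0.0], P=100.0, P0=0.0)
        base = m.simulate(init, (0.0, 200.0), n_points=50)
        tight = m.simulate(init, (0.0, 200.0), n_points=50,
                           solver=SolverOptions(rtol=1e-9, atol=1e-13))
        ref = np.abs(base.y[:, -1]) + 1e-12
        assert np.max(np.abs(base.y[:, -1] - tight.y[:, -1]) / ref) < 1e-3
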