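import numpy as np
import pytest

from cleftqsp import (
    TrialSpec,
    ValidationError,
    affinity_scan,
    get_antibody,
    get_disease,
    hypothetical_dose,
    run_trial,
    simulate_phase1_pd,
    target_engagement,
)
from cleftqsp.reproduce import q4w_regimen
from conftest import short_trial


class TestTargetEngagement:
    def test_free_at_baseline_gives_zero(self):
        te, mx = target_engagement(np.full(10, 4.2), 4.2)
        assert np.all(te == 0.0) and mx == 0.0

    def test_fully_depleted_gives_one(self):
        te, mx = target_engagement(np.zeros(10), 4.2)
        assert np.all(te == 1.0) and mx == 1.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValidationError):
            target_engagement(np.ones(3), 0.0)

    def test_clipped_to_unit_interval(self):
        te, _ = target_engagement(np.array([0.5, 2.0]), 1.0)
        assert te.min() >= 0.0 and te.max() <= 1.0


class TestPlaceboArm:
    def test_zero_dose_trial_has_no_effect(self):
        res = short_trial("gosuranemab", "tau-psp", 0.0, weeks=8.0, n_points=120)
        for key, value in res.metrics.items():
            if key.startswith(("max_te", "uptake_reduction")):
                assert abs(value) < 1e-6, key

    def test_placebo_free_levels_stay_at_baseline(self):
        res = short_trial("cinpanemab", "asyn-pd", 0.0, weeks=8.0, n_points=120)
        for col in ("cleft_monomer_nM", "cleft_oligomer_nM", "csf_monomer_nM"):
            series = res.placebo[col].to_numpy()
            assert np.max(np.abs(series / series[0] - 1)) < 1e-4


class TestEngagementGradient:
    @pytest.mark.parametrize("antibody, disease, result_fixture", [
        ("gosuranemab", "tau-psp", "gosuranemab_psp_trial"),
        ("cinpanemab", "asyn-pd", "cinpanemab_trials"),
    ])
    def test_te_decreases_from_csf_to_cleft(self, antibody, disease,
                                            result_fixture, request):
        res = request.getfixturevalue(result_fixture)
        if isinstance(res, dict):
            res = res[3500.0]
        m = res.metrics
        for sp in ("monomer", "oligomer"):
            assert m[f"max_te_csf_{sp}"] >= m[f"max_te_isf_{sp}"] - 1e-9
            assert m[f"max_te_isf_{sp}"] >= m[f"max_te_cleft_{sp}"] - 1e-9

    def test_tau_antibody_engages_csf_but_not_cleft_oligomer(self, gosuranemab_psp_trial):
        m = gosuranemab_psp_trial.metrics
        assert m["max_te_csf_monomer"] > 0.95
        assert m["max_te_cleft_oligomer"] < 0.1
        assert m["uptake_reduction_cumulative"] < 0.001

    def test_selective_asyn_antibody_engages_cleft_oligomer(self, cinpanemab_trials):
        m = cinpanemab_trials[3500.0].metrics
        assert m["max_te_cleft_oligomer"] > 0.5
        assert m["uptake_reduction_cumulative"] > 0.5
        # weak monomer affinity: little monomer engagement anywhere
        assert m["max_te_cleft_monomer"] < 0.2


class TestDoseAndAffinityOrdering:
    def test_uptake_reduction_monotone_along_dose_ladder(self, cinpanemab_trials):
        reductions = [cinpanemab_trials[d].metrics["uptake_reduction_cumulative"]
                      for d in (250.0, 1250.0, 3500.0)]
        assert reductions[0] < reductions[1] < reductions[2]
        tes = [cinpanemab_trials[d].metrics["max_te_cleft_oligomer"]
               for d in (250.0, 1250.0, 3500.0)]
        assert tes[0] < tes[1] < tes[2]

    def test_longer_half_life_gives_higher_trough_engagement(self):
        short = get_antibody("semorinemab")
        long = short.with_(half_life_h=800.0)
        results = {}
        for label, ab in (("short", short), ("long", long)):
            spec = TrialSpec(antibody=ab, disease=get_disease("tau-ad"),
                             regimen=q4w_regimen(4500.0, weeks=16.0))
            res = run_trial(spec, n_points=300)
            trough = res.treated["csf_monomer_nM"].to_numpy()[-1]
            results[label] = 1 - trough / res.baseline["csf_monomer_nM"]
        assert results["long"] > results["short"]

    def test_losing_oligomer_selectivity_collapses_cleft_engagement(self):
        selective = short_trial("cinpanemab", "asyn-pd", 3500.0)
        ab = get_antibody("cinpanemab").with_(kd_oligo=get_antibody("cinpanemab").kd_mono)
        spec = TrialSpec(antibody=ab, disease=get_disease("asyn-pd"),
                         regimen=q4w_regimen(3500.0, weeks=12.0))
        unselective = run_trial(spec, n_points=250)
        assert (unselective.metrics["max_te_cleft_oligomer"]
                < 0.2 * selective.metrics["max_te_cleft_oligomer"])

    def test_hypothetical_dose_equal_to_spec_dose_is_identical(self):
        spec = TrialSpec(antibody=get_antibody("tilavonemab"),
                         disease=get_disease("tau-psp"),
                         regimen=q4w_regimen(2000.0, weeks=12.0))
        a = run_trial(spec, n_points=200)
        b = hypothetical_dose(spec, 2000.0, n_points=200)
        assert a.metrics == b.metrics
        np.testing.assert_array_equal(a.treated.to_numpy(), b.treated.to_numpy())


class TestPhase1PD:
    def test_zero_dose_normalized_level_is_one(self):
        frame = simulate_phase1_pd("gosuranemab", [0.0], follow_up_weeks=6.0,
                                   n_points=100)
        np.testing.assert_allclose(frame["normalized_csf_monomer"], 1.0, atol=1e-6)

    def test_suppression_deepens_with_dose(self):
        frame = simulate_phase1_pd("gosuranemab", [210.0, 2100.0],
                                   follow_up_weeks=8.0, n_points=150)
        nadir = frame.groupby("dose_mg")["normalized_csf_monomer"].min()
        assert nadir[2100.0] < nadir[210.0]

    def test_empty_dose_panel_rejected(self):
        with pytest.raises(ValidationError):
            simulate_phase1_pd("gosuranemab", [])

    def test_weaker_affinity_gives_weaker_suppression_everywhere(self):
        """0.1 nM monomer affinity under-predicts the response of 0.02 nM."""
        tight = get_antibody("gosuranemab").with_(kd_mono=0.02, kd_oligo=0.02)
        weak = get_antibody("gosuranemab").with_(kd_mono=0.1, kd_oligo=0.1)
        f_tight = simulate_phase1_pd(tight, [700.0], follow_up_weeks=8.0, n_points=120)
        f_weak = simulate_phase1_pd(weak, [700.0], follow_up_weeks=8.0, n_points=120)
        early = f_tight["time_h"] > 24.0
        assert np.all(f_weak.loc[early, "normalized_csf_monomer"].to_numpy()
                      >= f_tight.loc[early, "normalized_csf_monomer"].to_numpy() - 1e-9)

    def test_affinity_scan_minimum_at_generating_affinity(self):
        truth = get_antibody("gosuranemab").with_(kd_mono=0.02, kd_oligo=0.02)
        data = simulate_phase1_pd(truth, [2100.0], follow_up_weeks=8.0, n_points=80)
        grid = np.array([0.005, 0.02, 0.1, 0.5])
        table = affinity_scan("gosuranemab", grid, data, follow_up_weeks=8.0,
                              n_points=80)
        best = table.loc[table["sse"].idxmin(), "kd_nM"]
        assert best == pytest.approx(0.02)
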