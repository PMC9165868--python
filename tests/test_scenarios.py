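import numpy as np
import pytest

from hepatolip.scenarios import (
    SweepSpec,
    _settle_run,
    agent_parameters,
    anti_pcsk9_scenario,
    baseline_scenario,
    combined_therapy_scenario,
    pcsk9_pulse_scenario,
    pcsk9_threshold_scan,
    recycling_fraction_comparison,
    run_sweep,
    statin_scenario,
)

SETTLE = 400.0  # shorter settle horizon keeps the suite fast; readouts are
                # numerically stationary well before this for every preset


class TestThresholdScan:
    def test_decoupled_pcsk9_yields_no_threshold(self, params):
        p = params.with_overrides(alpha_p=0.0)
        scan = pcsk9_threshold_scan(p, decades=(1e12, 1e14), settle_h=SETTLE)
        assert scan.threshold is None
        for _, ldl in scan.curve:
            assert ldl == pytest.approx(scan.baseline_ldl, rel=1e-8)

    def test_default_threshold_in_printed_bracket(self, params):
        scan = pcsk9_threshold_scan(params)
        assert scan.threshold is not None
        assert 1e12 <= scan.threshold <= 1e14

    def test_steady_ldl_nondecreasing_in_pcsk9(self, params):
        scan = pcsk9_threshold_scan(params, settle_h=SETTLE)
        ldl = [v for _, v in scan.curve]
        assert all(b >= a * (1 - 1e-9) for a, b in zip(ldl, ldl[1:]))

    def test_rejects_nonpositive_elevation(self, params):
        with pytest.raises(ValueError):
            pcsk9_threshold_scan(params, elevation_frac=0.0)


class TestStatin:
    def test_zero_dose_identical_to_baseline(self, params):
        run, metrics = statin_scenario(dose=0.0, params=params, settle_h=50.0)
        base = _settle_run(baseline_scenario(params, p_E0=1e12), 50.0)
        np.testing.assert_array_equal(run.y, base.y)
        assert metrics.pct_ldl_reduction == pytest.approx(0.0, abs=1e-12)

    def test_single_dose_reduces_ldl_and_upregulates_mrna(self, params):
        run_t, metrics = statin_scenario(params=params, settle_h=SETTLE)
        assert metrics.pct_ldl_reduction > 0
        assert metrics.pct_vldl_reduction > 0
        assert metrics.t_half_ldl_h > 10.0  # dosing happens at 10 h
        base = _settle_run(baseline_scenario(params, p_E0=1e12), SETTLE)
        for mrna in ("m_h", "m_r", "m_p"):
            assert run_t.component(mrna)[-1] > base.component(mrna)[-1]

    def test_free_hmgcr_monotone_in_dose(self, params):
        """Free HMGCR 2 h after dosing decreases with dose (5-point grid)."""
        doses = (0.0, 1e14, 5e14, 1e15, 5e15)
        h_12 = []
        for d in doses:
            run, _ = statin_scenario(dose=d, params=params, settle_h=50.0)
            idx = int(np.argmin(np.abs(run.time_h - 12.0)))
            h_12.append(run.component("h")[idx])
        assert all(b < a for a, b in zip(h_12, h_12[1:]))

    def test_influx_mode_close_to_bolus(self, params):
        _, m_b = statin_scenario(params=params, settle_h=200.0)
        _, m_i = statin_scenario(params=params, mode="influx", settle_h=200.0)
        assert m_i.pct_ldl_reduction == pytest.approx(
            m_b.pct_ldl_reduction, rel=0.05
        )


class TestAntiPcsk9:
    def test_zero_dose_equals_high_pcsk9_run(self, params):
        run, metrics = anti_pcsk9_scenario(dose=0.0, params=params,
                                           settle_h=50.0)
        assert metrics.pct_ldl_reduction == pytest.approx(0.0, abs=1e-12)

    def test_monotone_dose_response(self, params):
        reductions = []
        for dose in (1e13, 1e14, 1e15):
            _, m = anti_pcsk9_scenario(dose=dose, params=params,
                                       settle_h=SETTLE)
            reductions.append(m.pct_ldl_reduction)
        assert reductions[0] < reductions[1] < reductions[2]

    def test_small_molecule_dominates_antibody_pointwise(self, params):
        run_ab, m_ab = anti_pcsk9_scenario("antibody", params=params,
                                           settle_h=SETTLE)
        run_sm, m_sm = anti_pcsk9_scenario("small_molecule", params=params,
                                           settle_h=SETTLE)
        l_ab = run_ab.component("l_E")
        l_sm = run_sm.component("l_E")
        assert np.all(l_sm <= l_ab * (1 + 1e-9))
        assert m_sm.t_half_ldl_h <= m_ab.t_half_ldl_h
        assert m_sm.pct_ldl_reduction > m_ab.pct_ldl_reduction

    def test_agent_parameters(self, params):
        sm = agent_parameters(params, "small_molecule")
        assert sm.eps_p == pytest.approx(params.eps_p * 10)
        assert sm.eps_minus_p == pytest.approx(params.eps_minus_p / 10)
        with pytest.raises(ValueError):
            agent_parameters(params, "sirna")


class TestCombinedTherapy:
    def test_zero_doses_give_identical_baselines(self, params):
        metrics = combined_therapy_scenario(0.0, 0.0, params=params,
                                            settle_h=50.0)
        vals = [m.ldl_ss for m in metrics.values()]
        assert vals[0] == vals[1] == vals[2]
        assert all(m.pct_ldl_reduction == pytest.approx(0.0, abs=1e-9)
                   for m in metrics.values())

    def test_combined_below_each_monotherapy(self, params):
        metrics = combined_therapy_scenario(params=params, settle_h=SETTLE)
        combined = metrics["combined"]
        assert combined.ldl_ss <= metrics["statin"].ldl_ss * (1 + 1e-9)
        assert combined.ldl_ss <= metrics["antibody"].ldl_ss * (1 + 1e-9)
        assert combined.vldl_ss <= metrics["statin"].vldl_ss * (1 + 1e-9)
        assert combined.vldl_ss <= metrics["antibody"].vldl_ss * (1 + 1e-9)

    def test_additivity_band_on_dose_grid(self, params):
        """combined reduction >= max single and <= sum of singles."""
        # statin doses large enough to stay active through the readout;
        # antibody doses at or above the 1e14 PCSK9 load (sub-stoichiometric
        # antibody merely shelters PCSK9 in complex, breaking additivity)
        statins = (2e15, 3.5e15, 5e15)
        antibodies = (2e14, 5e14, 1e15)
        for sd in statins:
            for ad in antibodies:
                metrics = combined_therapy_scenario(sd, ad, params=params,
                                                    settle_h=300.0)
                singles = (metrics["statin"].pct_ldl_reduction,
                           metrics["antibody"].pct_ldl_reduction)
                comb = metrics["combined"].pct_ldl_reduction
                # slack: the 1:1 complex keeps a tiny equilibrium level of
                # free PCSK9, so near-total reductions can trail the best
                # monotherapy by a few thousandths of a point
                assert comb >= max(singles) - 0.05
                assert comb <= sum(singles) + 1e-6


class TestRecyclingComparison:
    def test_no_pcsk9_matches_default_f(self, params):
        pairs = recycling_fraction_comparison((0.0,), params=params,
                                              settle_h=200.0)
        assert pairs[0].matched
        assert pairs[0].f_matched == pytest.approx(params.f)

    def test_matched_f_decreases_with_pcsk9(self, params):
        pairs = recycling_fraction_comparison((1e13, 1e14), params=params,
                                              settle_h=SETTLE)
        assert all(p.matched for p in pairs)
        assert pairs[1].f_matched < pairs[0].f_matched <= params.f


class TestSweepsAndPresets:
    def test_sweep_spec_validation(self):
        with pytest.raises(ValueError):
            SweepSpec(name="p_E", values=(1.0, -2.0))
        with pytest.raises(ValueError):
            SweepSpec(name="p_E", values=(1.0,), kind="grid")

    def test_run_sweep_initial_concentration(self, params):
        curve = run_sweep(
            SweepSpec(name="p_E", values=(0.0, 1e14), settle_h=SETTLE),
            params,
        )
        assert curve[1][1] > curve[0][1]

    def test_pulse_scenario_event(self, params):
        s = pcsk9_pulse_scenario(params)
        (event,) = s.events
        assert event.mode == "influx"
        assert event.time_h == 100.0
        assert event.duration_h == pytest.approx(1.0 / 6.0)
        # 1e12 molec./mL delivered over 10 min
        assert event.amount * event.duration_h * 3600 == pytest.approx(1e12)
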