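"""Chamber drawdown: simulation, fitting, blanks and saturation rescaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meiox import (
    ChamberConfig,
    ChamberTrace,
    MonodParams,
    TraceDataError,
    blank_correct,
    fit_monod,
    fit_two_phase,
    monod_o2,
    respiration_at_saturation,
    round_half_up,
    saturation_rates,
    simulate_chamber,
    volumetric_to_specific,
)
from meiox.synth import gen_two_phase_trace

from conftest import monod_oracle

FIVE_MIN = 5.0 / 60.0


class TestSimulateChamber:
    def test_starts_at_initial_concentration(self, nematode1_params):
        tr = simulate_chamber(nematode1_params, np.arange(0.0, 2.0, FIVE_MIN))
        assert tr.o2_umol_l[0] == pytest.approx(nematode1_params.o2_init, abs=1e-6)

    def test_zero_order_limit_declines_linearly(self):
        # k_s → 0 collapses Monod to constant consumption until depletion
        p = MonodParams(r_max_vol=20.0, k_s=1e-6, o2_init=200.0)
        t = np.arange(0.0, 8.0, 0.25)
        tr = simulate_chamber(p, t)
        expected = np.clip(200.0 - 20.0 * t, 0.0, None)
        assert np.allclose(tr.o2_umol_l, expected, atol=1e-3)

    def test_matches_separable_ode_oracle(self, nematode1_params):
        t = np.arange(FIVE_MIN, 15.0, FIVE_MIN)
        ours = simulate_chamber(nematode1_params, t).o2_umol_l
        ref = monod_oracle(nematode1_params, t)
        assert np.max(np.abs(ours - ref) / ref) < 1e-6

    def test_mass_balance(self, nematode1_params):
        """O2 consumed equals the time integral of the instantaneous rate."""
        from scipy.integrate import quad

        p = nematode1_params
        t_end = 6.0
        tr = simulate_chamber(p, np.array([0.0, t_end]))
        consumed = p.o2_init - tr.o2_umol_l[-1]

        def rate(t):
            u = monod_o2(p, np.array([t]))[0] - p.o2_min
            return p.r_max_vol * u / (p.k_s + u)

        integral, _ = quad(rate, 0.0, t_end, limit=200)
        assert consumed == pytest.approx(integral, rel=1e-6)

    def test_decreasing_times_rejected(self, nematode1_params):
        with pytest.raises(ValueError):
            simulate_chamber(nematode1_params, [0.0, 1.0, 0.5])


class TestBlankCorrect:
    @staticmethod
    def _linear_trace(slope, cid="b", hours=10.0):
        t = np.arange(0.0, hours, 0.25)
        return ChamberTrace(t, np.clip(230.0 + slope * t, 0, None), cid, True)

    def test_zero_slope_blanks_leave_rate_unchanged(self):
        corr = blank_correct(20.0, [self._linear_trace(0.0)])
        assert corr.corrected_rate == pytest.approx(20.0)
        assert corr.blank_fraction == pytest.approx(0.0)

    def test_mean_of_two_blanks_subtracted(self):
        corr = blank_correct(
            20.0, [self._linear_trace(-1.0, "b1"), self._linear_trace(-3.0, "b2")]
        )
        assert corr.corrected_rate == pytest.approx(18.0)

    def test_contamination_flag_above_half(self):
        with pytest.warns(UserWarning, match="contamination"):
            corr = blank_correct(10.0, [self._linear_trace(-6.0)])
        assert corr.suspect_contamination

    def test_requires_a_blank(self):
        with pytest.raises(ValueError):
            blank_correct(20.0, [])


class TestFitMonod:
    def test_noise_free_self_consistency(self, nematode1_params):
        t = np.arange(0.0, 15.0, FIVE_MIN)
        tr = simulate_chamber(nematode1_params, t, method="analytic")
        fit = fit_monod(tr)
        assert fit.converged
        assert fit.params.k_s == pytest.approx(nematode1_params.k_s, rel=1e-4)
        assert fit.params.r_max_vol == pytest.approx(
            nematode1_params.r_max_vol, rel=1e-4
        )
        assert fit.params.o2_init == pytest.approx(
            nematode1_params.o2_init, rel=1e-4
        )

    def test_noisy_trace_recovers_within_ten_percent(self, nematode1_params):
        rng = np.random.default_rng(20130328)
        t = np.arange(0.0, 15.0, FIVE_MIN)
        clean = simulate_chamber(nematode1_params, t, method="analytic").o2_umol_l
        tr = ChamberTrace(t, np.clip(clean + rng.normal(0, 2.0, t.size), 0, None))
        fit = fit_monod(tr)
        assert fit.params.k_s == pytest.approx(nematode1_params.k_s, rel=0.10)
        assert fit.params.r_max_vol == pytest.approx(
            nematode1_params.r_max_vol, rel=0.10
        )

    def test_near_linear_trace_pins_ks_at_bound(self):
        p = MonodParams(r_max_vol=200.0, k_s=1e4, o2_init=230.0)
        t = np.arange(0.0, 10.0, FIVE_MIN)
        fit = fit_monod(simulate_chamber(p, t, method="analytic"))
        assert fit.params.k_s == pytest.approx(350.0, abs=1e-3)
        assert "k_s" in fit.bound_hits

    def test_rising_trace_is_a_data_error(self):
        t = np.arange(0.0, 2.0, FIVE_MIN)
        with pytest.raises(TraceDataError, match="decline"):
            fit_monod(ChamberTrace(t, 100.0 + 5.0 * t))

    def test_too_few_points_rejected(self):
        with pytest.raises(TraceDataError):
            fit_monod(ChamberTrace(np.arange(5.0), 100.0 - np.arange(5.0)))


class TestFitTwoPhase:
    MONOD = MonodParams(r_max_vol=40.0, k_s=60.0, o2_init=220.0)

    def test_breakpoint_recovered_within_one_interval(self):
        tr, truth = gen_two_phase_trace(
            self.MONOD,
            plateau_o2=110.0,
            plateau_hours=5.0,
            linear_rate_vol=25.0,
            seed=7,
        )
        res = fit_two_phase(tr)
        assert res.two_phase
        assert abs(res.breakpoint_h - truth["breakpoint_h"]) <= FIVE_MIN + 1e-9

    def test_supplied_breakpoint_slope_is_ols_of_tail(self):
        tr, truth = gen_two_phase_trace(
            self.MONOD,
            plateau_o2=110.0,
            plateau_hours=5.0,
            linear_rate_vol=25.0,
            seed=3,
        )
        bp = truth["breakpoint_h"]
        res = fit_two_phase(tr, breakpoint_h=bp)
        sel = tr.times_h >= bp
        slope = np.polyfit(tr.times_h[sel], tr.o2_umol_l[sel], 1)[0]
        assert res.linear_rate_vol == pytest.approx(-slope)

    def test_single_phase_trace_falls_back_with_flag(self, nematode1_params):
        t = np.arange(0.0, 15.0, FIVE_MIN)
        tr = simulate_chamber(nematode1_params, t, method="analytic")
        res = fit_two_phase(tr)
        assert not res.two_phase

    def test_config_converts_linear_rate_to_specific(self):
        tr, _ = gen_two_phase_trace(
            self.MONOD,
            plateau_o2=110.0,
            plateau_hours=5.0,
            linear_rate_vol=25.0,
            seed=1,
        )
        cfg = ChamberConfig(volume_l=3.0e-4, total_biomass_ugC=30.0)
        res = fit_two_phase(tr, cfg=cfg)
        assert res.linear_rate == pytest.approx(
            volumetric_to_specific(res.linear_rate_vol, cfg)
        )


class TestUnitConversion:
    def test_zero_rate_is_zero(self):
        cfg = ChamberConfig(volume_l=3.0e-4, total_biomass_ugC=50.0)
        assert volumetric_to_specific(0.0, cfg) == 0.0

    def test_doubling_biomass_halves_specific_rate(self):
        c1 = ChamberConfig(volume_l=3.0e-4, total_biomass_ugC=50.0)
        c2 = ChamberConfig(volume_l=3.0e-4, total_biomass_ugC=100.0)
        assert volumetric_to_specific(10.0, c1) == pytest.approx(
            2.0 * volumetric_to_specific(10.0, c2)
        )

    def test_nematode_chamber_arithmetic(self):
        # 63.8 µmol/l/h in 300 µl over 122.5 µg C → 0.045 µg C µg C⁻¹ d⁻¹
        cfg = ChamberConfig(volume_l=3.0e-4, total_biomass_ugC=122.5)
        assert round_half_up(volumetric_to_specific(63.8, cfg)) == 0.045

    def test_zero_biomass_rejected(self):
        with pytest.raises(ValueError):
            volumetric_to_specific(
                10.0, ChamberConfig(volume_l=3.0e-4, total_biomass_ugC=0.0)
            )


class TestRespirationAtSaturation:
    def test_full_saturation_is_anchor(self):
        assert respiration_at_saturation(0.045, 105.25, 100.0) == pytest.approx(
            0.045
        )

    @pytest.mark.parametrize(
        "r100,ks,pct,expected",
        [
            (0.027, 22.66, 10.0, 0.015),  # foraminifer, low sensitivity
            (0.045, 105.25, 1.0, 0.001),  # nematode, high sensitivity
        ],
    )
    def test_published_rescaling_examples(self, r100, ks, pct, expected):
        assert round_half_up(respiration_at_saturation(r100, ks, pct)) == expected

    @given(
        pct=st.floats(min_value=0.5, max_value=99.0),
        ks=st.floats(min_value=1.0, max_value=349.0),
    )
    @settings(deadline=None)
    def test_increasing_in_pct_and_decreasing_in_ks(self, pct, ks):
        lo = respiration_at_saturation(0.05, ks, pct)
        hi = respiration_at_saturation(0.05, ks, pct * 1.01)
        assert hi > lo
        # higher k_s ⇒ steeper decline below saturation
        assert respiration_at_saturation(0.05, ks + 1.0, pct) < lo

    def test_ordering_of_bundle(self):
        rates = saturation_rates(0.05, 50.0)
        assert rates.r_100 >= rates.r_10 >= rates.r_1 >= 0

    def test_negative_percent_rejected(self):
        with pytest.raises(ValueError):
            respiration_at_saturation(0.05, 50.0, -1.0)
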