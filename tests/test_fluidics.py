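"""Infusion-line digital twin: schedules, mixing, transport, balance."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import flowspec as fs
from flowspec.errors import FlowSpecError
from flowspec.fluidics import SALINE


def constant_schedule(sal, eg, tz, duration=3600.0):
    return fs.PumpSchedule.from_rate_table(
        [(0.0, duration, {SALINE: sal, "EG": eg, "TZ": tz})]
    )


STOCKS = {"EG": 25.0, "TZ": 100.0}


class TestPumpSchedule:
    def test_noncontiguous_segments_rejected(self):
        with pytest.raises(FlowSpecError) as exc:
            fs.Pump("EG", (fs.PumpSegment(0, 10, 1.0), fs.PumpSegment(20, 30, 2.0)))
        assert exc.value.code == "invalid_segment"

    def test_negative_rate_rejected(self):
        with pytest.raises(FlowSpecError):
            fs.PumpSegment(0, 10, -1.0)

    def test_rates_right_continuous_at_switch(self):
        pump = fs.Pump("EG", (fs.PumpSegment(0, 900, 3.0), fs.PumpSegment(900, 2100, 7.0)))
        np.testing.assert_allclose(pump.rates_at([899.0, 900.0, 901.0]), [3.0, 7.0, 7.0])

    def test_breakpoints_cover_phase_boundaries(self):
        sched = fs.preset("exp_b").schedule
        np.testing.assert_allclose(sched.breakpoints_s, [0.0, 900.0, 2100.0])


class TestJunctionConcentration:
    def test_constant_flow_fractions(self):
        # Q = (1.5, 0.5, 1.0) mL/h -> EG at 0.5/3 of stock, TZ at 1/3.
        c = fs.junction_concentration(
            {SALINE: 1.5, "EG": 0.5, "TZ": 1.0}, STOCKS
        )
        assert c["EG"] / STOCKS["EG"] == pytest.approx(0.167, abs=5e-4)
        assert c["TZ"] / STOCKS["TZ"] == pytest.approx(1 / 3, rel=1e-12)

    def test_post_switch_fraction(self):
        c = fs.junction_concentration({SALINE: 3.0, "EG": 7.0, "TZ": 3.0}, STOCKS)
        assert c["EG"] / STOCKS["EG"] == pytest.approx(0.54, abs=5e-3)

    def test_single_pump_delivers_stock(self):
        c = fs.junction_concentration({SALINE: 0.0, "EG": 2.0, "TZ": 0.0}, STOCKS)
        assert c["EG"] == STOCKS["EG"]
        assert c["TZ"] == 0.0

    def test_no_flow_rejected(self):
        with pytest.raises(FlowSpecError) as exc:
            fs.junction_concentration({SALINE: 0.0, "EG": 0.0}, STOCKS)
        assert exc.value.code == "no_flow"


class TestTransport:
    def run(self, schedule, line, detector=None, **kw):
        tz, eg = fs.default_dyes()
        detector = detector or fs.DetectorConfig(relative_noise_sd=0.0)
        return fs.simulate_line(
            schedule,
            line,
            (tz, eg),
            fs.FlowCellGeometry(),
            detector,
            balance_noise_sd=0.0,
            **kw,
        )[0]

    def test_plug_flow_delay_is_exactly_one_dead_volume(self):
        # Step at t = 900 s with Q_tot = 13 mL/h, V = 1 mL: the cell must not
        # change until V/Q = 276.9 s later (next sample: t = 1177 s).
        sched = fs.PumpSchedule.from_rate_table(
            [
                (0.0, 900.0, {SALINE: 7.0, "EG": 3.0, "TZ": 3.0}),
                (900.0, 2100.0, {SALINE: 3.0, "EG": 7.0, "TZ": 3.0}),
            ]
        )
        line = fs.LineConfig(dead_volume_ml=1.0, transport="plug")
        tr = self.run(sched, line)
        c_eg = tr.conc_true["EG"]
        lag_samples = int(np.ceil(1.0 / (13.0 / 3600.0)))
        pre_level = 3.0 / 13.0 * 25.0
        # fully settled before the switch arrives at the cell
        assert c_eg[900 + lag_samples - 1] == pytest.approx(pre_level, rel=1e-12)
        assert c_eg[900 + lag_samples] > pre_level + 1.0

    def test_noiseless_cumulative_mass_matches_closed_form(self):
        sched = fs.preset("exp_b").schedule
        line = fs.LineConfig()
        tr = self.run(sched, line)
        t = tr.time_s
        # piecewise-linear closed form: rho * (13 t for t<900; then 13*900 + 13(t-900))
        expected = np.where(
            t <= 900, 13.0 / 3600 * t, 13.0 / 3600 * t
        )  # Q_tot constant across the swap
        np.testing.assert_allclose(tr.mass_true_g, expected, rtol=1e-9, atol=1e-12)

    @pytest.mark.parametrize("n_tanks", [1, 3, 10])
    def test_steady_state_equals_junction_concentration(self, n_tanks):
        sched = constant_schedule(1.5, 0.5, 1.0, duration=6 * 3600.0)
        line = fs.LineConfig(dead_volume_ml=0.5, n_tanks=n_tanks)
        tr = self.run(sched, line)
        junction = fs.junction_concentration(
            {SALINE: 1.5, "EG": 0.5, "TZ": 1.0}, STOCKS
        )
        assert tr.conc_true["EG"][-1] == pytest.approx(junction["EG"], rel=1e-4)
        assert tr.conc_true["TZ"][-1] == pytest.approx(junction["TZ"], rel=1e-4)

    def test_step_response_is_monotone(self):
        sched = constant_schedule(3.0, 7.0, 3.0, duration=3600.0)
        for n_tanks in (1, 5):
            tr = self.run(sched, fs.LineConfig(n_tanks=n_tanks))
            assert np.all(np.diff(tr.conc_true["EG"]) >= -1e-12)

    def test_lag_scales_inversely_with_total_flow(self):
        # t50 * Q_tot should be constant (= f(n) * V) across flow totals.
        products = []
        for q in (3.0, 6.0, 12.0):
            sched = constant_schedule(q / 3, q / 3, q / 3, duration=4 * 3600.0)
            tr = self.run(sched, fs.LineConfig(dead_volume_ml=1.0))
            c = tr.conc_true["EG"]
            t50 = tr.time_s[np.searchsorted(c, 0.5 * c[-1])]
            products.append(t50 * q)
        assert np.ptp(products) / np.mean(products) < 0.05

    def test_solute_mass_is_conserved_in_transport(self):
        # Integrated solute flux at the cell plus the line's holdup equals the
        # injected mass.
        sched = constant_schedule(1.5, 0.5, 1.0, duration=6 * 3600.0)
        dead_volume = 0.5
        tr = self.run(sched, fs.LineConfig(dead_volume_ml=dead_volume))
        dt = tr.time_s[1] - tr.time_s[0]
        out_mass = np.sum(tr.conc_true["EG"] * tr.q_tot_ml_h / 3600.0) * dt
        holdup = dead_volume * tr.conc_true["EG"][-1]
        in_mass = 0.5 * 25.0 / 3600.0 * tr.time_s[-1]
        assert out_mass + holdup == pytest.approx(in_mass, rel=0.01)

    def test_unstable_timestep_rejected(self):
        sched = constant_schedule(7.0, 3.0, 3.0)
        line = fs.LineConfig(dead_volume_ml=0.01, n_tanks=10)
        with pytest.raises(FlowSpecError) as exc:
            self.run(sched, line)
        assert exc.value.code == "unstable_timestep"

    def test_trials_deterministic_under_seed(self):
        sched = constant_schedule(1.5, 0.5, 1.0, duration=600.0)
        tz, eg = fs.default_dyes()
        kw = dict(
            schedule=sched,
            line=fs.LineConfig(),
            dyes=(tz, eg),
            geometry=fs.FlowCellGeometry(),
            detector=fs.DetectorConfig(),
            n_trials=2,
            seed=7,
        )
        a = fs.simulate_line(**kw)
        b = fs.simulate_line(**kw)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.intensities[424.0], tb.intensities[424.0])
            np.testing.assert_array_equal(ta.mass_g, tb.mass_g)
        # distinct trials are not identical
        assert not np.array_equal(a[0].intensities[424.0], a[1].intensities[424.0])


class TestBalanceReadout:
    def test_zero_noise_gives_quantized_truth(self):
        m = np.array([0.0, 0.123456, 0.2])
        out = fs.balance_readout(m, balance_noise_sd=0.0, resolution=1e-5)
        assert out[1] == pytest.approx(0.12346, abs=1e-12)  # round-half-even
        np.testing.assert_allclose(out, np.round(m / 1e-5) * 1e-5)

    def test_round_half_even(self):
        # ties round to the even multiple of the resolution
        m = np.array([0.0, 0.75, 1.25])
        out = fs.balance_readout(m, balance_noise_sd=0.0, resolution=0.5)
        assert out[1] == pytest.approx(1.0)
        assert out[2] == pytest.approx(1.0)

    def test_monte_carlo_noise_magnitude(self):
        m = np.full(10_000, 1.0)
        out = fs.balance_readout(m, balance_noise_sd=1e-4, resolution=1e-7, seed=3)
        assert out.std(ddof=1) == pytest.approx(1e-4, rel=0.05)

    def test_decreasing_mass_rejected(self):
        with pytest.raises(FlowSpecError) as exc:
            fs.balance_readout(np.array([1.0, 0.5]))
        assert exc.value.code == "nonmonotone_mass"


@given(
    q_sal=st.floats(0.1, 20.0),
    q_eg=st.floats(0.0, 20.0),
    q_tz=st.floats(0.0, 20.0),
)
def test_junction_fractions_sum_to_one(q_sal, q_eg, q_tz):
    c = fs.junction_concentration({SALINE: q_sal, "EG": q_eg, "TZ": q_tz}, STOCKS)
    f_sal = q_sal / (q_sal + q_eg + q_tz)
    assert c["EG"] / 25.0 + c["TZ"] / 100.0 + f_sal == pytest.approx(1.0, rel=1e-12)
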