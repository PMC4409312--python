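"""Stimulation protocols: f-I, spike probability, f-V, trajectories,
interval-fraction probability, phase plane, SD scans."""

import math

import numpy as np
import pytest

from fluctmod.models import (ELIFParams, PassiveLIFParams,
                             holding_current, elif_rheobase, lif_isi)
from fluctmod.protocols import (ProtocolConfig, fi_protocol,
                                spike_probability_protocol, fv_protocol,
                                first_spike_trajectory, isi_trajectory,
                                interval_fraction_probability,
                                phase_plane_curve, voltage_sd_vs_mean,
                                find_dc_for_rate, ProtocolFailure,
                                step_transition_amplitude)
from fluctmod.analysis import (fraction_above_midpoint, ahp_half_duration,
                               fit_boltzmann)


class TestFIProtocol:
    def test_passive_rates_match_analytic_isi(self, passive):
        amps = np.arange(325.0, 600.0, 50.0)
        cfg = ProtocolConfig(step_amplitudes=amps, step_duration=2000.0)
        fi = fi_protocol(passive, cfg)
        for a, f in zip(amps, fi.y):
            expected = 1000.0 / lif_isi(passive, a)
            assert f == pytest.approx(expected, rel=0.02)

    def test_elif2_below_rheobase_all_missing(self, elif2):
        cfg = ProtocolConfig(step_amplitudes=np.arange(0.0, 320.0, 50.0),
                             step_duration=1000.0)
        fi = fi_protocol(elif2, cfg)
        assert np.all(np.isnan(fi.y))

    def test_deterministic_rates_nondecreasing(self, elif15):
        amps = np.arange(150.0, 650.0, 50.0)
        cfg = ProtocolConfig(step_amplitudes=amps, step_duration=1000.0)
        fi = fi_protocol(elif15, cfg)
        d = np.diff(fi.y[np.isfinite(fi.y)])
        assert np.all(d >= -1e-9)

    def test_zero_coefficient_equals_noise_off(self, elif15):
        amps = np.array([200.0, 400.0])
        a = fi_protocol(elif15, ProtocolConfig(step_amplitudes=amps,
                                               noise_coefficient=0.0))
        b = fi_protocol(elif15, ProtocolConfig(step_amplitudes=amps))
        np.testing.assert_array_equal(a.y, b.y)

    def test_bit_identical_given_seed(self, elif2, coeff2):
        amps = np.array([350.0])
        cfg = dict(step_amplitudes=amps, repeats=3,
                   noise_coefficient=coeff2, seed_base=5,
                   step_duration=500.0, pre_step_settle=200.0)
        a = fi_protocol(elif2, ProtocolConfig(**cfg))
        b = fi_protocol(elif2, ProtocolConfig(**cfg))
        np.testing.assert_array_equal(a.y_repeats, b.y_repeats)


class TestSpikeProbability:
    def test_deterministic_transition_within_one_step(self, elif2):
        amps = np.arange(200.0, 420.0, 10.0)
        cfg = ProtocolConfig(step_amplitudes=amps, step_duration=100.0)
        pi = spike_probability_protocol(elif2, cfg)
        assert set(np.unique(pi.y)) <= {0.0, 1.0}
        jumps = np.nonzero(np.diff(pi.y))[0]
        assert len(jumps) == 1

    def test_saturates_far_above_rheobase(self, elif2, coeff2):
        cfg = ProtocolConfig(step_amplitudes=np.array([600.0]),
                             step_duration=100.0, repeats=10,
                             noise_coefficient=coeff2, seed_base=2)
        pi = spike_probability_protocol(elif2, cfg)
        assert pi.y[0] == 1.0

    def test_estimate_consistent_with_high_repeat_rerun(self, elif2,
                                                        coeff2):
        """A 15-repeat probability estimate lies within 2 binomial SEs of
        a 90-repeat rerun."""
        trans = step_transition_amplitude(elif2, 100.0)
        amp = np.array([trans - 20.0])
        base = dict(step_amplitudes=amp, step_duration=100.0,
                    noise_coefficient=coeff2, pre_step_settle=500.0)
        p_small = spike_probability_protocol(
            elif2, ProtocolConfig(repeats=15, seed_base=11, **base)).y[0]
        p_big = spike_probability_protocol(
            elif2, ProtocolConfig(repeats=90, seed_base=12, **base)).y[0]
        se = math.sqrt(max(p_big * (1 - p_big), 0.25 / 90) / 15)
        assert abs(p_small - p_big) <= 2.5 * se


class TestFVProtocol:
    def test_passive_fv_slope_is_negative(self, passive):
        amps = np.arange(310.0, 500.0, 25.0)
        cfg = ProtocolConfig(step_amplitudes=amps, step_duration=2000.0)
        fv = fv_protocol(passive, cfg)
        ok = np.isfinite(fv.y)
        slope = np.polyfit(fv.x[ok], fv.y[ok], 1)[0]
        assert slope < 0

    def test_elif2_span_below_half_millivolt(self, elif2):
        from fluctmod.studies import fv_study
        st = fv_study(elif2, n_levels=15)
        assert st["span_mV"] <= 0.5


class TestTrajectories:
    def test_passive_first_spike_fraction_closed_form(self, passive):
        cfg = ProtocolConfig()
        traj = first_spike_trajectory(passive, cfg, target_latency=50.0)
        frac = fraction_above_midpoint(traj.t, traj.V_mean)
        tau = passive.C / passive.g
        lat = traj.meta["latency_ms"]
        expected = 1.0 - tau * math.log(2.0) / lat
        assert frac == pytest.approx(expected, rel=0.02)

    def test_elif15_trajectory_more_linear_than_passive(self, elif15,
                                                        passive):
        cfg = ProtocolConfig()
        f15 = fraction_above_midpoint(
            *_tv(first_spike_trajectory(elif15, cfg, 50.0)))
        fp = fraction_above_midpoint(
            *_tv(first_spike_trajectory(passive, cfg, 50.0)))
        assert f15 < fp

    def test_isi_cycle_period_near_target_rate(self, elif15):
        cfg = ProtocolConfig()
        cyc = isi_trajectory(elif15, cfg, target_rate=4.0)
        assert 235.0 <= cyc.meta["period_ms"] <= 270.0

    def test_large_slope_factor_lengthens_ahp(self, elif15, elif2):
        cfg = ProtocolConfig()
        halves = {}
        for name, p in (("e15", elif15), ("e2", elif2)):
            cyc = isi_trajectory(p, cfg, target_rate=4.0)
            halves[name] = ahp_half_duration(cyc.t, cyc.V_mean,
                                             cyc.meta["threshold_V"])
        assert halves["e15"] > halves["e2"]

    def test_unattainable_rate_raises(self, passive):
        with pytest.raises(ProtocolFailure):
            find_dc_for_rate(passive, 4.0, I_hi=100.0)


def _tv(traj):
    return traj.t, traj.V_mean


class TestIntervalFraction:
    def test_deterministic_probability_is_step(self, elif15):
        fr = np.array([0.1, 0.5, 0.75, 0.85, 0.99])
        curve = interval_fraction_probability(elif15, fr, n_trials=50,
                                              window=50.0,
                                              noise_coefficient=0.0)
        period = curve.meta["period_ms"]
        expected = (fr >= 1.0 - 50.0 / period).astype(float)
        np.testing.assert_array_equal(curve.y, expected)

    def test_small_slope_factor_boosts_mid_cycle_probability(
            self, elif2, elif15, coeff2, coeff15):
        fr = np.array([0.2, 0.45, 0.7])
        p2 = interval_fraction_probability(elif2, fr, n_trials=150,
                                           noise_coefficient=coeff2,
                                           seed_base=3).y
        p15 = interval_fraction_probability(elif15, fr, n_trials=150,
                                            noise_coefficient=coeff15,
                                            seed_base=4).y
        assert np.all(p2 > p15)

    def test_probability_nondecreasing_in_fraction(self, elif15,
                                                   coeff15):
        fr = np.arange(0.1, 1.0, 0.2)
        p = interval_fraction_probability(elif15, fr, n_trials=150,
                                          noise_coefficient=coeff15,
                                          seed_base=5).y
        se = np.sqrt(np.maximum(p * (1 - p), 0.25 / 150) / 150)
        assert np.all(np.diff(p) >= -2 * (se[:-1] + se[1:]))


class TestPhasePlane:
    def test_passive_line_has_slope_minus_g_over_c(self, passive):
        Vg = np.linspace(-80.0, -60.0, 21)
        pp = phase_plane_curve(passive, 0.0, Vg)
        slope = np.polyfit(pp.x, pp.y, 1)[0]
        assert slope == pytest.approx(-passive.g / passive.C, rel=1e-9)

    def test_elif_minimum_at_exponential_threshold(self, elif15):
        Vg = np.linspace(-80.0, -40.0, 4001)
        pp = phase_plane_curve(elif15, 100.0, Vg)
        assert pp.x[np.argmin(pp.y)] == pytest.approx(elif15.V_T,
                                                      abs=0.02)

    def test_dc_shifts_curve_by_delta_over_c(self, elif15):
        Vg = np.linspace(-80.0, -50.0, 31)
        a = phase_plane_curve(elif15, 100.0, Vg)
        b = phase_plane_curve(elif15, 250.0, Vg)
        np.testing.assert_allclose(b.y - a.y, 150.0 / elif15.C,
                                   rtol=1e-12)


class TestVoltageSD:
    def test_passive_sd_constant_across_means(self, passive):
        coeff = 300.0
        dcs = np.array([-50.0, 0.0, 50.0, 100.0])
        sd = voltage_sd_vs_mean(passive, dcs, coeff, duration_s=4.0)
        assert np.ptp(sd.y) / sd.y.mean() < 0.10

    def test_elif15_sd_grows_with_depolarization(self, elif15, coeff15):
        I_hold = holding_current(elif15, -75.0)
        dcs = I_hold + np.array([-100.0, 0.0, 80.0])
        sd = voltage_sd_vs_mean(elif15, dcs, coeff15, duration_s=5.0)
        assert np.all(np.diff(sd.y) > 0)
        assert np.all(np.diff(sd.x) > 0)
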