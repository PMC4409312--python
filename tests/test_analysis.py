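"""Spike statistics, curve fits and trajectory shape metrics."""

import math

import numpy as np
import pytest

from fluctmod.models import SpikeTrain, SimulationTrace
from fluctmod.analysis import (detect_spikes, spike_frequency_first3,
                               rheobase_from_steps, fit_linear_gain,
                               region_deltas, fit_boltzmann,
                               fit_power_law, fraction_above_midpoint,
                               ahp_half_duration, boltzmann, power_law,
                               MissingRheobase, FitFailure)


def _trace(V, dt=0.1):
    t = np.arange(len(V)) * dt
    return SimulationTrace(t=t, V=np.asarray(V, dtype=float),
                           spikes=SpikeTrain(np.empty(0)), dt=dt)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        tr = _trace(np.full(1000, -75.0))
        assert len(detect_spikes(tr)) == 0

    def test_two_bumps_give_two_spikes(self):
        V = np.full(1000, -70.0)
        V[100:120] = 10.0
        V[600:620] = 10.0
        tr = _trace(V)
        st = detect_spikes(tr, threshold=-20.0)
        assert len(st) == 2
        assert st.times[1] - st.times[0] == pytest.approx(50.0)

    def test_refractory_merges_rapid_recrossings(self):
        V = np.full(400, -70.0)
        V[100:105] = 0.0
        V[110:115] = 0.0  # 0.5 ms later: inside the refractory window
        tr = _trace(V)
        assert len(detect_spikes(tr, threshold=-20.0, refractory=2.0)) == 1


class TestSpikeFrequency:
    def test_uniform_isis(self):
        st = SpikeTrain(np.array([0.0, 250.0, 500.0, 750.0]))
        assert spike_frequency_first3(st) == pytest.approx(4.0)

    def test_mean_of_reciprocals(self):
        st = SpikeTrain(np.array([0.0, 100.0, 300.0, 700.0]))
        assert spike_frequency_first3(st) == pytest.approx(
            (10.0 + 5.0 + 2.5) / 3.0)

    def test_reciprocal_of_mean_variant(self):
        st = SpikeTrain(np.array([0.0, 100.0, 300.0, 700.0]))
        assert spike_frequency_first3(st, reciprocal_of_mean=True) == \
            pytest.approx(3000.0 / 700.0)

    def test_three_spikes_is_undefined(self):
        assert spike_frequency_first3(
            SpikeTrain(np.array([0.0, 10.0, 20.0]))) is None


class TestRheobaseFromSteps:
    def test_first_qualifying_amplitude(self):
        amps = np.array([100.0, 125.0, 150.0, 175.0])
        counts = np.array([0, 2, 5, 9])
        assert rheobase_from_steps(amps, counts) == 150.0

    def test_median_over_repeats(self):
        amps = np.array([100.0, 150.0])
        counts = np.array([[0, 0, 6], [3, 5, 8]])
        assert rheobase_from_steps(amps, counts) == 150.0

    def test_all_subthreshold_raises(self):
        with pytest.raises(MissingRheobase):
            rheobase_from_steps(np.array([10.0]), np.array([1]))


class TestLinearGain:
    def test_exact_line_recovered(self):
        I = np.arange(100.0, 400.0, 25.0)
        m = fit_linear_gain(I, 0.1 * I - 3.0)
        assert m.gain == pytest.approx(0.1, rel=1e-9)
        assert m.gain_r2 == pytest.approx(1.0)

    def test_missing_points_are_ignored(self):
        I = np.array([100.0, 200.0, 300.0, 400.0])
        m = fit_linear_gain(I, [None, 5.0, 15.0, 25.0])
        assert m.gain == pytest.approx(0.1, rel=1e-9)

    def test_insufficient_points_raise(self):
        with pytest.raises(FitFailure):
            fit_linear_gain(np.array([1.0, 2.0, 3.0]), [None, None, 4.0])


class TestRegionDeltas:
    def test_zero_noise_gives_zero_deltas(self):
        amps = np.arange(0.0, 300.0, 25.0)
        rates = [None if a < 100 else 0.2 * (a - 100) for a in amps]
        out = region_deltas(amps, rates, rates, rheobase=100.0)
        assert out == {"low": 0.0, "mid": 0.0, "high": 0.0}

    def test_low_delta_is_difference_at_rheobase(self):
        amps = np.arange(0.0, 300.0, 25.0)
        det = [None if a < 100 else 0.2 * (a - 100) for a in amps]
        noisy = [(0.0 if a < 100 else 0.2 * (a - 100)) + 7.0 for a in amps]
        out = region_deltas(amps, det, noisy, rheobase=100.0)
        assert out["low"] == pytest.approx(7.0)

    def test_short_deterministic_span_drops_high_region(self):
        amps = np.array([0.0, 50.0, 100.0])
        det = [None, 2.0, 10.0]   # spans only 8 spikes/s above onset
        noisy = [1.0, 4.0, 12.0]
        out = region_deltas(amps, det, noisy, rheobase=50.0)
        assert out["high"] is None


class TestBoltzmannFit:
    def test_noiseless_recovery_to_four_digits(self):
        I = np.arange(100.0, 320.0, 10.0)
        P = boltzmann(I, 200.0, 25.0)
        fit = fit_boltzmann(I, P)
        assert fit.I_half == pytest.approx(200.0, rel=1e-4)
        assert fit.k == pytest.approx(25.0, rel=1e-4)
        assert fit.r2 > 0.9999

    def test_p02_equals_direct_inversion(self):
        I = np.arange(0.0, 400.0, 20.0)
        fit = fit_boltzmann(I, boltzmann(I, 180.0, 30.0))
        # invert P = 0.2 on the fitted curve
        inv = fit.I_half + fit.k * math.log(0.2 / 0.8)
        assert fit.P02_current == pytest.approx(inv, abs=1e-12)
        assert boltzmann(fit.P02_current, fit.I_half, fit.k) == \
            pytest.approx(0.2, abs=1e-12)

    def test_binomial_sampling_recovery(self, rng):
        """25-repeat binomial sampling from a known curve: Monte-Carlo
        mean of the estimates stays within ~2 MC standard errors."""
        I = np.arange(100.0, 320.0, 10.0)
        truth = boltzmann(I, 200.0, 25.0)
        est = []
        for _ in range(200):
            P = rng.binomial(25, truth) / 25.0
            fit = fit_boltzmann(I, P)
            est.append((fit.I_half, fit.k))
        est = np.array(est)
        for j, true_val in enumerate((200.0, 25.0)):
            mean = est[:, j].mean()
            se = est[:, j].std(ddof=1) / math.sqrt(len(est))
            assert abs(mean - true_val) < max(3 * se, 0.02 * true_val)

    def test_step_curve_flagged_degenerate(self):
        I = np.arange(0.0, 200.0, 20.0)
        P = (I >= 100.0).astype(float)
        fit = fit_boltzmann(I, P)
        assert fit.degenerate


class TestPowerLawFit:
    def test_noiseless_recovery(self):
        V = np.linspace(-69.0, -59.0, 25)
        f = power_law(V, 2.0, -70.0, 1.5, 0.0)
        fit = fit_power_law(V, f)
        assert fit.p == pytest.approx(1.5, abs=0.01)
        assert fit.r2 > 0.9999

    def test_noiseless_bias_below_two_percent(self, rng):
        for p_true in (1.2, 1.78, 2.5):
            V = np.linspace(-68.0, -56.0, 30)
            f = power_law(V, 1.5, -70.0, p_true, 2.0)
            fit = fit_power_law(V, f)
            assert abs(fit.p - p_true) / p_true < 0.02

    def test_linear_data_fits_unit_exponent(self):
        V = np.linspace(-70.0, -60.0, 20)
        f = 4.0 * (V + 72.0)
        fit = fit_power_law(V, f)
        assert fit.p == pytest.approx(1.0, abs=0.05)

    def test_scale_bound_respected(self):
        V = np.linspace(-70.0, -60.0, 20)
        f = 0.001 * (V + 71.0) ** 3
        fit = fit_power_law(V, f)
        assert fit.a >= 1.0


class TestTrajectoryMetrics:
    def test_linear_ramp_fraction_is_half(self):
        t = np.linspace(0.0, 50.0, 5001)
        V = -75.0 + 0.4 * t
        assert fraction_above_midpoint(t, V) == pytest.approx(0.5,
                                                              abs=0.001)

    def test_exponential_fraction_closed_form(self):
        """Exponential approach, tau = 10 ms over T = 50 ms:
        fraction = 1 - tau ln2 / T."""
        t = np.linspace(0.0, 50.0, 50001)
        V = -55.0 - 20.0 * np.exp(-t / 10.0)
        expected = 1.0 - 10.0 * math.log(2.0) / 50.0
        assert fraction_above_midpoint(t, V) == pytest.approx(expected,
                                                              abs=0.005)

    def test_linear_rise_half_duration(self):
        t = np.linspace(0.0, 200.0, 2001)
        V = -80.0 + 0.1 * t  # reaches -60 at 200 ms
        assert ahp_half_duration(t, V, threshold_V=-60.0) == \
            pytest.approx(100.0, abs=0.2)

    def test_exponential_rise_half_duration(self):
        """Exponential rise with tau = 30 ms toward an asymptote equal to
        threshold: midpoint crossed at 30 ln2 ms."""
        t = np.linspace(0.0, 300.0, 30001)
        V = -60.0 - 20.0 * np.exp(-t / 30.0)
        out = ahp_half_duration(t, V, threshold_V=-60.0)
        assert out == pytest.approx(30.0 * math.log(2.0), abs=0.1)

    def test_midpoint_never_crossed_returns_none(self):
        t = np.linspace(0.0, 100.0, 1001)
        V = np.full_like(t, -80.0)
        assert ahp_half_duration(t, V, threshold_V=-60.0) is None
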