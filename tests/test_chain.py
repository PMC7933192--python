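"""Signal-chain model: two-exponential kernel, pole-zero cancellation,
lowpass filtering, equivalent bandwidth, clipping and bias droop."""

import numpy as np
import pytest

from sipmsim import (
    BiasSupplyParams,
    ImpulseResponseParams,
    InputDomainError,
    SampledTrace,
    TransferFunction,
    apply_lowpass,
    apply_pzc,
    bias_droop,
    clip_amplifier,
    equivalent_bandwidth,
    impulse_response,
    lowpass_transfer_function,
)

FS = 2e9  # fine grid that resolves the sub-ns fast component
PARAMS = ImpulseResponseParams(
    fast_time_constant_s=1.2e-9, slow_time_constant_s=18e-9, slow_to_fast_charge_ratio=10.0
)


class TestImpulseResponse:
    def test_charge_split_ten_to_one(self):
        """With charge ratio 10 the slow component carries 10/11 of the total."""
        k = impulse_response(PARAMS, FS, gain=1.0, duration_s=400e-9)
        t = k.times_s
        slow = (
            PARAMS.slow_to_fast_charge_ratio
            / (1 + PARAMS.slow_to_fast_charge_ratio)
            / PARAMS.slow_time_constant_s
            * np.exp(-t / PARAMS.slow_time_constant_s)
        )
        q_slow = np.trapezoid(slow, t)
        q_total = np.trapezoid(k.samples, t)
        assert q_slow / q_total == pytest.approx(10 / 11, rel=5e-3)

    def test_zero_ratio_is_single_exponential(self):
        p = ImpulseResponseParams(1.2e-9, 18e-9, slow_to_fast_charge_ratio=0.0)
        k = impulse_response(p, FS, duration_s=50e-9)
        t = k.times_s
        expected = np.exp(-t / p.fast_time_constant_s) / p.fast_time_constant_s
        np.testing.assert_allclose(k.samples, expected, rtol=1e-12)

    @pytest.mark.parametrize("gain", [1.0, 12.9])
    def test_kernel_integral_equals_gain(self, gain):
        k = impulse_response(PARAMS, FS, gain=gain, duration_s=500e-9)
        assert np.trapezoid(k.samples, dx=1 / FS) == pytest.approx(gain, rel=5e-3)

    def test_unresolved_fast_component_warns(self):
        with pytest.warns(UserWarning, match="fast component"):
            impulse_response(PARAMS, 125e6)

    def test_invalid_params_rejected(self):
        with pytest.raises(InputDomainError):
            ImpulseResponseParams(fast_time_constant_s=20e-9, slow_time_constant_s=10e-9)


class TestPZC:
    def test_matched_zero_removes_slow_component(self):
        """Zero at the slow pole: energy remaining beyond one slow time
        constant is < 1% of the original slow-component energy."""
        t = np.arange(int(400e-9 * FS)) / FS
        slow = SampledTrace(np.exp(-t / 18e-9), FS)
        out = apply_pzc(slow, 18e-9, attenuation=0.1)
        tail = t > 18e-9
        assert np.sum(out.samples[tail] ** 2) < 0.01 * np.sum(slow.samples[tail] ** 2)

    def test_mismatched_zero_partial_fraction_residue(self):
        """tau_z = 0.8 tau_s leaves a slow exponential whose amplitude is the
        partial-fraction residue (1 - tz/ts) / (1/a - tz/ts)."""
        a, ts = 0.1, 18e-9
        tz = 0.8 * ts
        t = np.arange(int(400e-9 * FS)) / FS
        out = apply_pzc(SampledTrace(np.exp(-t / ts), FS), tz, a)
        late = (t > 3 * ts) & (t < 6 * ts)
        measured = np.exp(np.mean(np.log(out.samples[late]) + t[late] / ts))
        expected = (1 - tz / ts) / (1 / a - tz / ts)
        assert measured == pytest.approx(expected, rel=1e-3)

    def test_fast_component_passes_unchanged(self):
        """A fast exponential well inside the PZC passband (tau_f much
        shorter than the residual pole a*tau_z) passes with unity gain."""
        fs, tau_f = 1e11, 0.05e-9
        t = np.arange(int(100e-9 * fs)) / fs
        x = SampledTrace(np.exp(-t / tau_f), fs)
        out = apply_pzc(x, 18e-9, attenuation=0.3)
        n2 = int(2 * tau_f * fs)
        assert out.samples[:n2] == pytest.approx(x.samples[:n2], rel=0.05)

    def test_bad_args(self):
        t = SampledTrace(np.zeros(8), FS)
        with pytest.raises(InputDomainError):
            apply_pzc(t, -1e-9, 0.1)
        with pytest.raises(InputDomainError):
            apply_pzc(t, 18e-9, 0.0)


class TestLowpass:
    def test_dc_gain_unity(self):
        trace = SampledTrace(np.full(50_000, 7.0), 125e6)
        out = apply_lowpass(trace, 25e6)
        assert out.samples[5000:].mean() == pytest.approx(7.0, rel=1e-6)

    @pytest.mark.parametrize("family", ["butterworth", "brickwall"])
    def test_white_noise_variance_scales_by_equivalent_bandwidth(self, family, rng):
        """Parseval: filtered/unfiltered white-noise variance equals the
        filter's equivalent bandwidth within 2% on a 1e6-sample trace."""
        wn = SampledTrace(rng.standard_normal(1_000_000), 125e6)
        out = apply_lowpass(wn, 25e6, family=family)
        eb = equivalent_bandwidth(lowpass_transfer_function(25e6, 125e6, family=family), 125e6)
        ratio = out.samples[2000:].var() / wn.samples.var()
        assert ratio == pytest.approx(eb, rel=0.02)

    def test_near_nyquist_cutoff_near_identity(self, rng):
        wn = SampledTrace(rng.standard_normal(100_000), 125e6)
        out = apply_lowpass(wn, 62.4e6, family="brickwall")
        assert out.samples.var() == pytest.approx(wn.samples.var(), rel=0.01)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        trace = SampledTrace(np.zeros(100), 125e6)
        with pytest.raises(InputDomainError):
            apply_lowpass(trace, 62.5e6)


class TestEquivalentBandwidth:
    def test_brickwall_25_over_62p5_is_exactly_0p4(self):
        tf = TransferFunction.brickwall(25e6, 62.5e6)
        assert equivalent_bandwidth(tf, 125e6) == pytest.approx(0.4, abs=1e-15)

    def test_allpass_is_one(self):
        tf = TransferFunction(np.array([0.0, 62.5e6]), np.array([1.0, 1.0]))
        assert equivalent_bandwidth(tf, 125e6) == pytest.approx(1.0, abs=1e-15)

    def test_single_pole_closed_form(self):
        f_c, f_n = 10e6, 62.5e6
        tf = TransferFunction.single_pole(f_c, f_n, n=200_001)
        expected = f_c * np.arctan(f_n / f_c) / f_n
        assert equivalent_bandwidth(tf, 125e6) == pytest.approx(expected, rel=1e-6)

    def test_grid_must_cover_nyquist(self):
        tf = TransferFunction(np.linspace(0, 50e6, 100), np.ones(100))
        with pytest.raises(InputDomainError):
            equivalent_bandwidth(tf, 125e6)

    def test_in_unit_interval_for_normalized_lowpass(self):
        for fc in [1e6, 10e6, 60e6]:
            tf = TransferFunction.single_pole(fc, 62.5e6)
            assert 0 < equivalent_bandwidth(tf, 125e6) <= 1

    def test_file_roundtrip(self, tmp_path):
        tf = TransferFunction.single_pole(10e6, 62.5e6, n=101)
        tf.to_file(tmp_path / "tf.txt")
        back = TransferFunction.from_file(tmp_path / "tf.txt")
        np.testing.assert_allclose(back.frequency_hz, tf.frequency_hz)
        np.testing.assert_allclose(back.magnitude_sq, tf.magnitude_sq)


class TestClipAmplifier:
    def test_infinite_rails_identity(self):
        trace = SampledTrace(np.sin(np.arange(100.0)), 125e6)
        out, frac = clip_amplifier(trace, -np.inf, np.inf)
        assert np.array_equal(out.samples, trace.samples)
        assert frac == 0.0

    def test_all_samples_above_rail(self):
        trace = SampledTrace(np.full(100, 10.0), 125e6)
        out, frac = clip_amplifier(trace, -1.0, 1.0)
        assert np.all(out.samples == 1.0)
        assert frac == 1.0

    def test_dc_offset_shifts_before_clipping(self):
        trace = SampledTrace(np.array([0.0, 0.5]), 125e6)
        out, _ = clip_amplifier(trace, 0.2, 1.0, dc_offset=0.4)
        np.testing.assert_allclose(out.samples, [0.4, 0.9])

    def test_voltage_domain_clips_an_order_of_magnitude_earlier(self):
        """Without PZC the amplifier sees the full 11/11 of the photon
        charge; a current-domain PZC (divider attenuation 1/11, matching the
        fast-charge fraction) passes only the fast component, so for
        identical rails the voltage-domain chain clips at ~10x lower flux."""
        from scipy.signal import fftconvolve

        fs = 2e9
        kernel = impulse_response(PARAMS, fs, gain=1.0, duration_s=300e-9)
        atten = 1 / (1 + PARAMS.slow_to_fast_charge_ratio)
        rng = np.random.default_rng(0)
        duration = 3e-6
        n = int(duration * fs)
        fluxes = np.geomspace(1e8, 3e11, 16)
        max_voltage, max_current = [], []
        for flux in fluxes:
            n_ph = rng.poisson(flux * duration)
            bins = np.bincount(
                (rng.uniform(0, duration, n_ph) * fs).astype(int), minlength=n
            )[:n]
            v = fftconvolve(bins * fs, kernel.samples / fs)[:n]
            c = apply_pzc(SampledTrace(v, fs), PARAMS.slow_time_constant_s, atten)
            # steady-state half of the trace: settled amplifier level
            max_voltage.append(v[n // 2 :].max())
            max_current.append(c.samples[n // 2 :].max())
        rail = 1e10
        onset_v = np.interp(np.log(rail), np.log(max_voltage), np.log(fluxes))
        onset_c = np.interp(np.log(rail), np.log(max_current), np.log(fluxes))
        assert 8 < np.exp(onset_c - onset_v) < 14


class TestBiasDroop:
    def test_zero_and_knee_are_unity(self):
        supply = BiasSupplyParams()
        assert bias_droop(0.0, supply) == 1.0
        assert bias_droop(supply.max_current_a, supply) == 1.0

    def test_monotone_nonincreasing_in_current(self):
        supply = BiasSupplyParams(max_current_a=10e-3)
        currents = np.linspace(0, 0.1, 200)
        scales = [bias_droop(i, supply) for i in currents]
        assert all(b <= a + 1e-15 for a, b in zip(scales, scales[1:]))
        assert scales[-1] < 1.0
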