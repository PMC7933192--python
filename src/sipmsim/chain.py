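"""Analog signal-chain model: SiPM impulse response, pole-zero cancellation,
lowpass filtering, amplifier clipping, bias-supply droop, and equivalent
bandwidth.

The SiPM single-photon response is modeled as a two-exponential kernel: a
fast component (array capacitance discharging into the amplifier) and a slow
component (individual microcell recharge through its quench resistor)
carrying ~10x more charge.  Pole-zero cancellation (PZC) places a zero in
the amplifier transfer function at the recharge pole, converting the large
slow tail into a small fast residual so the amplifier dynamic range is spent
on the fast signal component.

Equivalent bandwidth is the integrated power of a (DC-normalized) transfer
function relative to an ideal brick-wall filter at the Nyquist frequency; it
is the factor by which analog filtering reduces the variance of white shot
noise, and enters the photon-transfer-curve flux formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import InputDomainError, SampledTrace

__all__ = [
    "ImpulseResponseParams",
    "TransferFunction",
    "BiasSupplyParams",
    "impulse_response",
    "apply_pzc",
    "apply_lowpass",
    "lowpass_transfer_function",
    "equivalent_bandwidth",
    "clip_amplifier",
    "bias_droop",
]


@dataclass(frozen=True)
class ImpulseResponseParams:
    """Two-exponential SiPM single-photon response.

    ``slow_to_fast_charge_ratio`` is the ratio of integrated charge carried
    by the slow (recharge) component to the fast component; ~10 for typical
    devices.  Time-constant defaults are representative values (the fast
    term is sub-nanosecond, the slow term is the tens-of-ns recharge).
    """

    fast_time_constant_s: float = 0.8e-9
    slow_time_constant_s: float = 18e-9
    slow_to_fast_charge_ratio: float = 10.0

    def __post_init__(self) -> None:
        if not self.fast_time_constant_s > 0 or not self.slow_time_constant_s > 0:
            raise InputDomainError("time constants must be > 0")
        if self.slow_time_constant_s <= self.fast_time_constant_s:
            raise InputDomainError("slow_time_constant_s must exceed fast_time_constant_s")
        if self.slow_to_fast_charge_ratio < 0:
            raise InputDomainError("slow_to_fast_charge_ratio must be >= 0")


@dataclass
class TransferFunction:
    """Frequency-domain magnitude-squared response, normalized to 1 at DC
    (or in the passband plateau)."""

    frequency_hz: np.ndarray
    magnitude_sq: np.ndarray

    def __post_init__(self) -> None:
        self.frequency_hz = np.asarray(self.frequency_hz, dtype=np.float64)
        self.magnitude_sq = np.asarray(self.magnitude_sq, dtype=np.float64)
        if self.frequency_hz.shape != self.magnitude_sq.shape or self.frequency_hz.ndim != 1:
            raise InputDomainError("frequency and magnitude grids must be equal-length 1-D arrays")
        if self.frequency_hz.size < 2:
            raise InputDomainError("need at least two frequency points")
        if np.any(self.frequency_hz < 0) or np.any(np.diff(self.frequency_hz) < 0):
            raise InputDomainError("frequencies must be nonnegative and ascending")
        if np.any(self.magnitude_sq < 0) or not np.all(np.isfinite(self.magnitude_sq)):
            raise InputDomainError("magnitude-squared response must be finite and nonnegative")

    @classmethod
    def brickwall(cls, cutoff_hz: float, f_max_hz: float) -> "TransferFunction":
        """Ideal unit-height brick-wall lowpass on [0, cutoff]. The grid
        carries a duplicated point at the cutoff so trapezoid integration of
        the discontinuity is exact."""
        if not 0 < cutoff_hz <= f_max_hz:
            raise InputDomainError("require 0 < cutoff_hz <= f_max_hz")
        if cutoff_hz == f_max_hz:
            return cls(np.array([0.0, f_max_hz]), np.array([1.0, 1.0]))
        f = np.array([0.0, cutoff_hz, cutoff_hz, f_max_hz])
        h2 = np.array([1.0, 1.0, 0.0, 0.0])
        return cls(f, h2)

    @classmethod
    def single_pole(cls, corner_hz: float, f_max_hz: float, n: int = 4097) -> "TransferFunction":
        f = np.linspace(0.0, f_max_hz, n)
        return cls(f, 1.0 / (1.0 + (f / corner_hz) ** 2))

    @classmethod
    def from_ba(cls, b, a, sample_rate_hz: float, n: int = 4097) -> "TransferFunction":
        """Magnitude-squared response of a digital filter up to Nyquist."""
        w, h = sps.freqz(b, a, worN=np.linspace(0.0, sample_rate_hz / 2.0, n), fs=sample_rate_hz)
        return cls(w, np.abs(h) ** 2)

    def to_file(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.frequency_hz, self.magnitude_sq]),
            header="frequency_hz magnitude_sq",
        )

    @classmethod
    def from_file(cls, path) -> "TransferFunction":
        data = np.loadtxt(path)
        return cls(data[:, 0], data[:, 1])


@dataclass(frozen=True)
class BiasSupplyParams:
    """High-voltage bias generator limits (10 mA into a ~50 V load)."""

    max_current_a: float = 10e-3
    bias_voltage_v: float = 50.0

    def __post_init__(self) -> None:
        if not self.max_current_a > 0:
            raise InputDomainError("max_current_a must be > 0")


def impulse_response(
    params: ImpulseResponseParams,
    sample_rate_hz: float,
    gain: float = 1.0,
    duration_s: float | None = None,
) -> SampledTrace:
    """Sampled two-exponential kernel ``A_f exp(-t/tau_f) + A_s exp(-t/tau_s)``.

    Amplitudes are chosen so the integrated charges satisfy
    ``A_s tau_s : A_f tau_f = slow_to_fast_charge_ratio : 1`` and the total
    integral equals ``gain``.  A warning is emitted if the sampling rate does
    not resolve the fast component (< 2 samples per fast time constant).
    """
    if not sample_rate_hz > 0:
        raise InputDomainError("sample_rate_hz must be > 0")
    if sample_rate_hz * params.fast_time_constant_s < 2.0:
        warnings.warn(
            "sample rate does not resolve the fast component "
            f"({sample_rate_hz * params.fast_time_constant_s:.2f} samples per fast tau); "
            "the discretized kernel aliases the fast term",
            stacklevel=2,
        )
    if duration_s is None:
        duration_s = 10.0 * params.slow_time_constant_s
    r = params.slow_to_fast_charge_ratio
    q_fast = gain / (1.0 + r)
    q_slow = gain * r / (1.0 + r)
    a_fast = q_fast / params.fast_time_constant_s
    a_slow = q_slow / params.slow_time_constant_s
    t = np.arange(int(np.ceil(duration_s * sample_rate_hz))) / sample_rate_hz
    h = a_fast * np.exp(-t / params.fast_time_constant_s) + a_slow * np.exp(
        -t / params.slow_time_constant_s
    )
    return SampledTrace(samples=h, sample_rate_hz=float(sample_rate_hz))


def _pzc_ba(pzc_time_constant_s: float, attenuation: float, sample_rate_hz: float):
    # Continuous prototype H(s) = a (tau_z s + 1) / (a tau_z s + 1):
    # unity gain at high frequency (fast pulse passes), gain `a` at DC, zero
    # at 1/tau_z cancelling the recharge pole.  Discretized by bilinear
    # transform.
    tz = pzc_time_constant_s
    a = attenuation
    return sps.bilinear([a * tz, a], [a * tz, 1.0], fs=sample_rate_hz)


def apply_pzc(
    trace: SampledTrace,
    pzc_time_constant_s: float,
    attenuation: float = 0.1,
) -> SampledTrace:
    """Pole-zero cancellation filter.

    Places a transfer-function zero at ``1/pzc_time_constant_s``.  When the
    zero matches a decaying exponential's pole exactly, that component is
    replaced by a residual with the much shorter time constant
    ``attenuation * pzc_time_constant_s`` — the slow recharge tail is
    suppressed while the fast component passes with unity gain.

    ``attenuation`` in (0, 1] is the DC gain of the filter, i.e. the factor
    by which the shunt divider attenuates slow/DC current.
    """
    if not pzc_time_constant_s > 0:
        raise InputDomainError("pzc_time_constant_s must be > 0")
    if not 0 < attenuation <= 1:
        raise InputDomainError("attenuation must lie in (0, 1]")
    b, a = _pzc_ba(pzc_time_constant_s, attenuation, trace.sample_rate_hz)
    return trace.with_samples(sps.lfilter(b, a, trace.samples))


def apply_lowpass(
    trace: SampledTrace,
    cutoff_hz: float,
    order: int = 4,
    family: str = "butterworth",
) -> SampledTrace:
    """Lowpass filter the trace (anti-alias / bandwidth-matching stage).

    ``family`` is ``"butterworth"`` (default, causal IIR) or ``"brickwall"``
    (ideal FFT-domain truncation, used for analytic tests).
    """
    nyq = trace.sample_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise InputDomainError(f"cutoff_hz must lie in (0, Nyquist={nyq:g}), got {cutoff_hz}")
    if family == "butterworth":
        b, a = sps.butter(order, cutoff_hz, fs=trace.sample_rate_hz)
        return trace.with_samples(sps.lfilter(b, a, trace.samples))
    if family == "brickwall":
        spec = np.fft.rfft(trace.samples)
        f = np.fft.rfftfreq(trace.n_samples, d=1.0 / trace.sample_rate_hz)
        spec[f > cutoff_hz] = 0.0
        return trace.with_samples(np.fft.irfft(spec, n=trace.n_samples))
    raise InputDomainError(f"unknown filter family {family!r}")


def lowpass_transfer_function(
    cutoff_hz: float,
    sample_rate_hz: float,
    order: int = 4,
    family: str = "butterworth",
    n: int = 8193,
) -> TransferFunction:
    """Transfer function of the filter applied by :func:`apply_lowpass`."""
    if family == "butterworth":
        b, a = sps.butter(order, cutoff_hz, fs=sample_rate_hz)
        return TransferFunction.from_ba(b, a, sample_rate_hz, n=n)
    if family == "brickwall":
        return TransferFunction.brickwall(cutoff_hz, sample_rate_hz / 2.0)
    raise InputDomainError(f"unknown filter family {family!r}")


def equivalent_bandwidth(tf: TransferFunction, sample_rate_hz: float) -> float:
    """Integrated power of ``tf`` relative to a Nyquist brick-wall.

    Returns ``integral(|H|^2, 0..fs/2) / (fs/2)``, the fraction by which the
    analog chain reduces white-noise variance relative to an ideal
    brick-wall filter of unit height at half the sampling rate.  Trapezoid
    integration on the provided grid; grid density is the caller's
    responsibility.
    """
    f_nyq = sample_rate_hz / 2.0
    f, h2 = tf.frequency_hz, tf.magnitude_sq
    if f[0] > 0 or f[-1] < f_nyq:
        raise InputDomainError(
            f"transfer-function grid [{f[0]:g}, {f[-1]:g}] does not cover [0, {f_nyq:g}]"
        )
    mask = f <= f_nyq
    f_cut = f[mask]
    h_cut = h2[mask]
    if f_cut[-1] < f_nyq:
        h_end = np.interp(f_nyq, f, h2)
        f_cut = np.append(f_cut, f_nyq)
        h_cut = np.append(h_cut, h_end)
    return float(np.trapezoid(h_cut, f_cut) / f_nyq)


def clip_amplifier(
    trace: SampledTrace,
    rail_low: float,
    rail_high: float,
    dc_offset: float = 0.0,
) -> tuple[SampledTrace, float]:
    """Shift by ``dc_offset`` then clamp to the amplifier rails.

    Returns the clipped trace and the fraction of samples that hit a rail.
    """
    if not rail_low < rail_high:
        raise InputDomainError("rail_low must be below rail_high")
    shifted = trace.samples + dc_offset
    clipped = np.clip(shifted, rail_low, rail_high)
    frac = float(np.mean((shifted <= rail_low) | (shifted >= rail_high))) if trace.n_samples else 0.0
    return trace.with_samples(clipped), frac


def bias_droop(mean_current_a: float, supply: BiasSupplyParams) -> float:
    """Effective overvoltage scale under bias-supply current limiting.

    Soft-knee model: unity up to the supply's current limit, then a smooth
    hyperbolic roll-off ``1 / (1 + (I/I_max - 1))`` beyond it, standing in
    for the gradual bias-voltage drop of a current-limited generator.
    Optional — a chain without a supply section never calls this.
    """
    if mean_current_a < 0:
        raise InputDomainError("mean_current_a must be >= 0")
    excess = mean_current_a / supply.max_current_a - 1.0
    if excess <= 0:
        return 1.0
    return 1.0 / (1.0 + excess)
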