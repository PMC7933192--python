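"""Shared containers and error types.

The central in-memory object is :class:`SampledTrace`: a uniformly sampled
detector output record.  The default 125 MHz sampling rate mirrors the
digitizer rate of resonant-scanning two-photon systems, for which one sample
spans 8 ns — comparable to a microcell recharge time, so a single sample bin
may contain several avalanche charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_SAMPLE_RATE_HZ = 125e6


class InputDomainError(ValueError):
    """An argument lies outside the physically meaningful domain."""


class ConsistencyError(ValueError):
    """Two inputs that must describe the same device/run disagree."""


class InsufficientDataError(ValueError):
    """Not enough samples/points to compute the requested quantity."""


@dataclass
class SampledTrace:
    """Uniformly sampled detector output.

    Parameters
    ----------
    samples
        Output values per sample bin.  For raw Monte Carlo traces the unit is
        charge (DN) deposited within the bin; after convolution with an
        amplifier kernel the unit is amplitude (DN).
    sample_rate_hz
        Sampling rate; 125 MHz by default.
    t0_s
        Absolute time of the first sample.
    discard_prefix_s
        Seconds of settling data already removed from the front of the trace
        (bookkeeping only; see :func:`sipmsim.montecarlo.trim_settling`).
    """

    samples: np.ndarray
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    t0_s: float = 0.0
    discard_prefix_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InputDomainError("samples must be one-dimensional")
        if not self.sample_rate_hz > 0:
            raise InputDomainError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise InputDomainError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        """Left edge of each sample bin."""
        return self.t0_s + np.arange(self.n_samples) / self.sample_rate_hz

    def with_samples(self, samples: np.ndarray, **changes) -> "SampledTrace":
        """Copy of this trace with new sample values (metadata preserved)."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64), **changes)
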