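"""Steady-state fluorophore excitation under a pulsed laser.

A fluorophore with single-exponential lifetime ``tau`` is excited by a pulse
train of period ``T = 1/repetition_rate``.  Writing ``x`` for the excited
fraction immediately after a pulse and ``p`` for the per-pulse excitation
probability of a ground-state molecule, one period of evolution gives the
recursion

    x' = x e^(-T/tau) + p (1 - x e^(-T/tau))

whose fixed point is ``x* = p / (1 - (1 - p) e^(-T/tau))``.  Photons emitted
per fluorophore per second: ``R * x* * (1 - e^(-T/tau))``.

The "10% excited" operating target can be pinned to three different
quantities (the conventions differ only when ``T`` is not >> ``tau``):

* ``per_pulse``      — each pulse excites 10% of ground-state molecules
  (p = 0.1);
* ``post_pulse``     — the post-pulse excited fraction is 10% (x* = 0.1);
  the default;
* ``time_averaged``  — the time-averaged excited fraction is 10%.  Under
  this convention the fluorescent yield per second is exactly
  ``target/tau`` independent of repetition rate (closed form), so it cannot
  produce any rate dependence of yield and is not the default.

Two-photon power bookkeeping: excitation probability per pulse scales as
pulse energy squared at fixed pulse width, so the pulse energy required for
a given ``p`` scales as sqrt(p) and the average power as
``repetition_rate * sqrt(p)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import InputDomainError, InsufficientDataError

__all__ = [
    "FluorophoreParams",
    "ExcitationParams",
    "SteadyState",
    "steady_state",
    "repetition_sweep",
    "twophoton_signal",
    "saturation_power",
    "pulse_energy",
]

CONVENTIONS = ("per_pulse", "post_pulse", "time_averaged")


@dataclass(frozen=True)
class FluorophoreParams:
    """Single-exponential fluorophore and its excitation operating target."""

    lifetime_s: float = 3e-9
    excitation_constraint: str = "post_pulse"
    target_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not self.lifetime_s > 0:
            raise InputDomainError("lifetime_s must be > 0")
        if self.excitation_constraint not in CONVENTIONS:
            raise InputDomainError(
                f"excitation_constraint must be one of {CONVENTIONS}, "
                f"got {self.excitation_constraint!r}"
            )
        if not 0.0 < self.target_fraction < 1.0:
            raise InputDomainError("target_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class ExcitationParams:
    """Pulsed-laser bookkeeping; pulse_energy = average_power / rep_rate."""

    repetition_rate_hz: float
    average_power_w: float | None = None
    pulse_energy_j: float | None = None

    def __post_init__(self) -> None:
        if not self.repetition_rate_hz > 0:
            raise InputDomainError("repetition_rate_hz must be > 0")
        if self.average_power_w is not None and self.pulse_energy_j is not None:
            expected = self.average_power_w / self.repetition_rate_hz
            if not np.isclose(self.pulse_energy_j, expected, rtol=1e-9):
                raise InputDomainError(
                    "pulse_energy_j must equal average_power_w / repetition_rate_hz"
                )


@dataclass
class SteadyState:
    per_pulse_fraction: float  # p: fraction of ground-state molecules excited per pulse
    excited_fraction: float  # x*: excited fraction immediately after a pulse
    yield_photons_per_s: float  # photons per fluorophore per second


def steady_state(rep_rate_hz: float, fl: FluorophoreParams) -> SteadyState:
    """Solve the pulse-train recursion under the configured constraint.

    The recursion is affine in ``x`` so its fixed point has an exact closed
    form; no iteration is needed.
    """
    if not rep_rate_hz > 0:
        raise InputDomainError("rep_rate_hz must be > 0")
    T = 1.0 / rep_rate_hz
    decay = np.exp(-T / fl.lifetime_s)  # excited fraction surviving one period
    t = fl.target_fraction

    if fl.excitation_constraint == "per_pulse":
        p = t
        x = p / (1.0 - (1.0 - p) * decay)
    elif fl.excitation_constraint == "post_pulse":
        x = t
        p = x * (1.0 - decay) / (1.0 - x * decay)
    else:  # time_averaged: mean of x e^(-t/tau) over one period equals t
        emitted_frac = -np.expm1(-T / fl.lifetime_s)
        x = t * T / (fl.lifetime_s * emitted_frac)
        if x >= 1.0:
            raise InputDomainError(
                f"time-averaged target {t} unreachable at {rep_rate_hz:g} Hz "
                f"with lifetime {fl.lifetime_s:g} s (needs excited fraction {x:.3f} >= 1)"
            )
        p = x * (1.0 - decay) / (1.0 - x * decay)
    if not 0.0 <= p <= 1.0:
        raise InputDomainError(
            f"constraint unsatisfiable: required per-pulse excitation {p:.4g} outside [0, 1]"
        )
    yield_per_s = rep_rate_hz * x * (1.0 - decay)
    return SteadyState(float(p), float(x), float(yield_per_s))


def repetition_sweep(
    rates_hz: Sequence[float],
    fl: FluorophoreParams,
    reference_rate_hz: float = 78e6,
) -> pd.DataFrame:
    """Relative fluorescent yield and required average power versus rate.

    Yield is normalized to the reference repetition rate (78 MHz, the
    standard Ti:Sapphire rate).  The required average power assumes the
    two-photon law (per-pulse excitation ~ pulse energy squared):
    ``power ~ rate * sqrt(p)``, also normalized to the reference.
    """
    ref = steady_state(reference_rate_hz, fl)
    rows = []
    for r in rates_hz:
        st = steady_state(r, fl)
        rows.append(
            {
                "repetition_rate_hz": float(r),
                "relative_yield": st.yield_photons_per_s / ref.yield_photons_per_s,
                "relative_power": (r / reference_rate_hz)
                * np.sqrt(st.per_pulse_fraction / ref.per_pulse_fraction),
            }
        )
    return pd.DataFrame(rows)


def twophoton_signal(power_w, coefficient: float = 1.0):
    """Unsaturated two-photon signal: ``coefficient * power**2``."""
    power = np.asarray(power_w, dtype=np.float64)
    if np.any(power < 0):
        raise InputDomainError("power must be >= 0")
    out = coefficient * power**2
    return float(out) if np.isscalar(power_w) else out


def saturation_power(
    powers_w: Sequence[float],
    signals: Sequence[float],
    deviation_threshold: float = 0.1,
    reference_decades: float = 1.0,
) -> tuple[float | None, np.ndarray]:
    """Lowest power deviating >10% from the intensity-squared law.

    A squared-law coefficient is fit (through-origin least squares on
    signal vs power^2) over the lowest ``reference_decades`` of the power
    grid; the deviation ``1 - signal/(c P^2)`` is interpolated in log-power
    for the threshold crossing.  Returns ``(power or None, deviations)``.
    """
    P = np.asarray(list(powers_w), dtype=np.float64)
    S = np.asarray(list(signals), dtype=np.float64)
    if P.shape != S.shape:
        raise InputDomainError("power and signal grids must be aligned")
    if P.size < 3:
        raise InsufficientDataError(f"need >= 3 grid points, got {P.size}")
    if np.any(P <= 0) or np.any(np.diff(P) <= 0):
        raise InputDomainError("powers must be positive and strictly ascending")

    ref_mask = P <= P[0] * 10.0**reference_decades
    p2 = P[ref_mask] ** 2
    c = float(np.sum(p2 * S[ref_mask]) / np.sum(p2 * p2))
    deviation = 1.0 - S / (c * P**2)

    above = deviation >= deviation_threshold
    if not above.any():
        return None, deviation
    i = int(np.argmax(above))
    if i == 0:
        return float(P[0]), deviation
    x0, x1 = np.log10(P[i - 1]), np.log10(P[i])
    y0, y1 = deviation[i - 1], deviation[i]
    crossing = 10 ** (x0 + (deviation_threshold - y0) * (x1 - x0) / (y1 - y0))
    return float(crossing), deviation


def pulse_energy(average_power_w: float, rep_rate_hz: float) -> float:
    """Energy per pulse in joules: average power / repetition rate."""
    if not rep_rate_hz > 0:
        raise InputDomainError("rep_rate_hz must be > 0")
    if average_power_w < 0:
        raise InputDomainError("average_power_w must be >= 0")
    return average_power_w / rep_rate_hz
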