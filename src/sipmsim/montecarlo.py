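"""Event-driven Monte Carlo model of a SiPM microcell array.

A silicon photomultiplier is an array of Geiger-mode avalanche photodiodes
("microcells"), each in series with a quench resistor.  A detected photon
triggers an avalanche that dumps the cell's stored charge into the output
node and leaves the cell empty; the cell then recharges through its quench
resistor with time constant ``tau_rc = Rq * Cj``.  A photon striking a
partially recharged cell releases charge proportional to the cell's current
charge state — the microscopic origin of pile-up nonlinearity at high flux.

The simulation is exact event-driven: Poisson photon arrivals are thinned by
the photon detection efficiency (PDE), assigned to microcells, and each
avalanche releases ``single_cell_gain * (1 - exp(-dt/tau_rc))`` where ``dt``
is the time since that cell last fired (a never-fired cell is fully charged
and releases exactly ``single_cell_gain``).  Released charge is accumulated
into the sample bin containing the arrival time, reproducing a digitizer
recording at the configured sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_SAMPLE_RATE_HZ,
    ConsistencyError,
    InputDomainError,
    InsufficientDataError,
    SampledTrace,
)

__all__ = [
    "SiPMDeviceParams",
    "PhotonArrivals",
    "simulate_arrivals",
    "simulate_response",
    "trim_settling",
    "detected_fraction_curve",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SiPMDeviceParams:
    """Static physical description of a SiPM microcell array.

    ``recharge_time_constant_s`` may be given directly or derived as
    ``quench_resistance_ohm * junction_capacitance_f``.  Defaults describe a
    representative 3 mm, 25 um-pitch device (see :mod:`sipmsim.reference`);
    they are datasheet-order estimates, not measured values.
    """

    n_microcells: int = 14400
    quench_resistance_ohm: float = 150e3
    junction_capacitance_f: float = 0.12e-12
    recharge_time_constant_s: float | None = None
    pde: float = 0.4
    single_cell_gain: float = 12.9
    overvoltage_v: float = 7.0
    dark_count_rate_hz: float = 0.0
    illumination_profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        if int(self.n_microcells) < 1:
            raise InputDomainError(f"n_microcells must be >= 1, got {self.n_microcells}")
        object.__setattr__(self, "n_microcells", int(self.n_microcells))
        if not 0.0 <= self.pde <= 1.0:
            raise InputDomainError(f"pde must lie in [0, 1], got {self.pde}")
        if self.recharge_time_constant_s is None:
            tau = self.quench_resistance_ohm * self.junction_capacitance_f
            object.__setattr__(self, "recharge_time_constant_s", tau)
        if not self.recharge_time_constant_s > 0:
            raise InputDomainError(
                f"recharge_time_constant_s must be > 0, got {self.recharge_time_constant_s}"
            )
        if not self.single_cell_gain > 0:
            raise InputDomainError(f"single_cell_gain must be > 0, got {self.single_cell_gain}")
        if self.dark_count_rate_hz < 0:
            raise InputDomainError("dark_count_rate_hz must be >= 0")
        if self.illumination_profile is not None:
            w = np.asarray(self.illumination_profile, dtype=np.float64)
            if w.shape != (self.n_microcells,):
                raise ConsistencyError(
                    f"illumination_profile has {w.size} weights for {self.n_microcells} microcells"
                )
            if np.any(w < 0) or not np.all(np.isfinite(w)):
                raise InputDomainError("illumination_profile weights must be finite and nonnegative")
            s = w.sum()
            if s <= 0:
                raise InputDomainError("illumination_profile weights must not all be zero")
            object.__setattr__(self, "illumination_profile", w / s)

    @property
    def tau_rc_s(self) -> float:
        return float(self.recharge_time_constant_s)


@dataclass
class PhotonArrivals:
    """Time-ordered detected photon arrivals with microcell assignments.

    ``true_flux_hz`` is the *launched* flux (before PDE thinning);
    ``n_launched`` is the Poisson-drawn number of launched photons, of which
    ``len(times_s)`` survived thinning (plus any dark counts).
    """

    times_s: np.ndarray
    cell_ids: np.ndarray
    duration_s: float
    true_flux_hz: float
    n_launched: int = 0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        if self.times_s.shape != self.cell_ids.shape:
            raise ConsistencyError("times_s and cell_ids must have equal length")
        if not self.duration_s > 0:
            raise InputDomainError(f"duration_s must be > 0, got {self.duration_s}")
        if self.times_s.size:
            if np.any(np.diff(self.times_s) < 0):
                raise ConsistencyError("arrival times must be nondecreasing")
            if self.times_s[0] < 0 or self.times_s[-1] > self.duration_s:
                raise ConsistencyError("arrival times must lie within [0, duration_s]")

    @property
    def n_detected(self) -> int:
        return int(self.times_s.size)


def _draw_cells(rng: np.random.Generator, n: int, device: SiPMDeviceParams) -> np.ndarray:
    if device.illumination_profile is None:
        return rng.integers(0, device.n_microcells, size=n)
    # Inverse-CDF draw; rng.choice is O(n_cells) per draw for weighted arrays.
    cdf = np.cumsum(device.illumination_profile)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(n), side="right")


def simulate_arrivals(
    flux_hz: float,
    duration_s: float,
    seed,
    device: SiPMDeviceParams,
) -> PhotonArrivals:
    """Draw detected photon arrivals for a homogeneous Poisson flux.

    Launched photons are Poisson(``flux_hz * duration_s``); each is detected
    independently with probability ``device.pde`` (thinning applied before
    cell assignment), and detected photons land on microcells drawn from the
    illumination profile.  Optional dark counts (``device.dark_count_rate_hz``,
    default 0) are added as an independent Poisson process, not thinned.
    """
    if flux_hz < 0:
        raise InputDomainError(f"flux_hz must be >= 0, got {flux_hz}")
    if not duration_s > 0:
        raise InputDomainError(f"duration_s must be > 0, got {duration_s}")
    rng = _as_rng(seed)

    n_launched = int(rng.poisson(flux_hz * duration_s))
    n_det = int(rng.binomial(n_launched, device.pde)) if n_launched else 0
    times = rng.uniform(0.0, duration_s, size=n_det)

    if device.dark_count_rate_hz > 0:
        n_dark = int(rng.poisson(device.dark_count_rate_hz * duration_s))
        times = np.concatenate([times, rng.uniform(0.0, duration_s, size=n_dark)])
    times.sort(kind="stable")
    cells = _draw_cells(rng, times.size, device)
    return PhotonArrivals(
        times_s=times,
        cell_ids=cells,
        duration_s=float(duration_s),
        true_flux_hz=float(flux_hz),
        n_launched=n_launched,
    )


def avalanche_charges(arrivals: PhotonArrivals, device: SiPMDeviceParams) -> np.ndarray:
    """Per-photon released charge, in arrival order.

    Each cell starts fully charged; an avalanche releases
    ``gain * (1 - exp(-dt/tau))`` and resets that cell's recharge clock.
    """
    if arrivals.cell_ids.size and (
        arrivals.cell_ids.min() < 0 or arrivals.cell_ids.max() >= device.n_microcells
    ):
        raise ConsistencyError("cell_ids out of range for this device")
    n = arrivals.n_detected
    if n == 0:
        return np.empty(0, dtype=np.float64)

    order = np.lexsort((arrivals.times_s, arrivals.cell_ids))
    t_sorted = arrivals.times_s[order]
    c_sorted = arrivals.cell_ids[order]

    dt = np.empty(n, dtype=np.float64)
    dt[0] = np.inf
    dt[1:] = t_sorted[1:] - t_sorted[:-1]
    first_on_cell = np.empty(n, dtype=bool)
    first_on_cell[0] = True
    np.not_equal(c_sorted[1:], c_sorted[:-1], out=first_on_cell[1:])
    dt[first_on_cell] = np.inf  # never-fired cell: fully charged

    charge_sorted = -np.expm1(-dt / device.tau_rc_s)
    charge_sorted *= device.single_cell_gain

    charges = np.empty(n, dtype=np.float64)
    charges[order] = charge_sorted
    return charges


def simulate_response(
    arrivals: PhotonArrivals,
    device: SiPMDeviceParams,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
) -> SampledTrace:
    """Accumulate avalanche charges into digitizer sample bins.

    Each photon's released charge is assigned wholly to the bin containing
    its arrival time (no sub-sample interpolation), so total trace charge
    equals total released charge exactly.
    """
    if not sample_rate_hz > 0:
        raise InputDomainError("sample_rate_hz must be > 0")
    charges = avalanche_charges(arrivals, device)
    n_bins = max(int(np.ceil(arrivals.duration_s * sample_rate_hz)), 1)
    idx = np.minimum((arrivals.times_s * sample_rate_hz).astype(np.int64), n_bins - 1)
    samples = np.bincount(idx, weights=charges, minlength=n_bins)
    return SampledTrace(samples=samples, sample_rate_hz=float(sample_rate_hz))


def trim_settling(
    trace: SampledTrace,
    device: SiPMDeviceParams,
    n_constants: float = 50,
) -> SampledTrace:
    """Drop the first ``n_constants`` recharge time constants of samples.

    The leading portion of a trace reflects the array's approach to its
    steady-state charge distribution (cells start fully charged here, as
    after a dark interval) and biases sample statistics; discarding 50
    recharge time constants leaves the stationary segment.
    """
    if n_constants < 0:
        raise InputDomainError("n_constants must be >= 0")
    window_s = n_constants * device.tau_rc_s
    k = int(np.ceil(window_s * trace.sample_rate_hz))
    if k == 0:
        return trace
    if k >= trace.n_samples:
        raise InsufficientDataError(
            f"trace of {trace.n_samples} samples is shorter than the "
            f"{k}-sample settling window ({n_constants} x tau_rc)"
        )
    return trace.with_samples(
        trace.samples[k:],
        t0_s=trace.t0_s + k / trace.sample_rate_hz,
        discard_prefix_s=trace.discard_prefix_s + k / trace.sample_rate_hz,
    )


def detected_fraction_curve(
    device: SiPMDeviceParams,
    flux_grid_hz: Sequence[float],
    duration_s: float,
    seeds: Sequence[int],
) -> pd.DataFrame:
    """Charge yield vs launched flux: the pile-up saturation curve.

    For each flux the ratio ``total released charge / (gain * n_launched *
    pde)`` is averaged over seeds.  In the dilute limit every detected photon
    finds a full cell and the ratio is 1; as the per-cell arrival interval
    approaches ``tau_rc`` the ratio falls below 1 (pile-up).

    Returns a DataFrame with columns ``launched_flux_hz``,
    ``detected_fraction`` and ``standard_error`` (over seeds; NaN for a
    single seed).
    """
    flux = np.asarray(list(flux_grid_hz), dtype=np.float64)
    if flux.size == 0 or np.any(flux <= 0):
        raise InputDomainError("flux_grid_hz must be positive")
    if np.any(np.diff(flux) <= 0):
        raise InputDomainError("flux_grid_hz must be strictly ascending")
    seeds = list(seeds)
    if not seeds:
        raise InputDomainError("at least one seed is required")

    rows = []
    for f in flux:
        ratios = []
        for s in seeds:
            arr = simulate_arrivals(f, duration_s, s, device)
            if arr.n_launched == 0:
                continue
            total = avalanche_charges(arr, device).sum()
            ratios.append(total / (device.single_cell_gain * arr.n_launched * device.pde))
        if not ratios:
            raise InsufficientDataError(
                f"no photons launched at flux {f:g}/s over {duration_s:g} s; increase duration"
            )
        ratios = np.asarray(ratios)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios)) if len(ratios) > 1 else np.nan
        rows.append((f, ratios.mean(), se))
    return pd.DataFrame(rows, columns=["launched_flux_hz", "detected_fraction", "standard_error"])
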