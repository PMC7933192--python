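"""Scanned-image formation and shot-noise SNR accounting.

Per-pixel SNR is defined as the mean pixel value divided by the standard
deviation of that pixel across sequential frames.  For a shot-noise-limited
detector collecting ``n`` photons per pixel the SNR is ``sqrt(n)``; a PMT's
stochastic electron multiplication inflates the variance by the excess
noise factor ``F``, giving ``sqrt(n/F)``.  A detector that saturates at
``phi_sat`` photons/s imaging at ``r`` pixels/s therefore has a hard ceiling
of ``sqrt(phi_sat / r)`` on single-frame SNR — the bound that motivates
high-dynamic-range detectors for resonant-scanning microscopy.

Resonant scanners sweep sinusoidally, so the instantaneous pixel rate peaks
at the sweep center; for pixels spaced uniformly in position across a
digitized fraction ``ff`` of the sweep amplitude, peak/average rate is
``arcsin(ff)/ff`` (-> pi/2 for the full sweep, -> 1 for a vanishing center
cut).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InputDomainError, InsufficientDataError
from .montecarlo import SiPMDeviceParams

__all__ = [
    "ScanGeometry",
    "PMTParams",
    "ImageStats",
    "max_shot_noise_snr",
    "pmt_snr",
    "frames_to_match_snr",
    "resonant_pixel_rates",
    "synthesize_frames",
    "per_pixel_snr",
    "sipm_pileup_transform",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Resonant-scan raster geometry."""

    line_rate_hz: float = 24000.0
    pixels_per_line: int = 2048
    lines_per_frame: int = 2048
    fill_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (self.line_rate_hz > 0 and self.pixels_per_line > 0 and self.lines_per_frame > 0):
            raise InputDomainError("scan geometry fields must be positive")
        if not 0.0 < self.fill_fraction <= 1.0:
            raise InputDomainError("fill_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class PMTParams:
    """PMT noise/saturation description.

    ``excess_noise_factor`` has no default: it is device- and gain-dependent
    and must be supplied.  ``saturation_flux_hz`` defaults to the ~3e9
    photons/s overcurrent-protection limit typical of GaAsP PMTs.
    """

    excess_noise_factor: float
    saturation_flux_hz: float = 3e9
    quantum_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if not self.excess_noise_factor >= 1.0:
            raise InputDomainError("excess_noise_factor must be >= 1")
        if not self.saturation_flux_hz > 0:
            raise InputDomainError("saturation_flux_hz must be > 0")
        if not 0.0 <= self.quantum_efficiency <= 1.0:
            raise InputDomainError("quantum_efficiency must lie in [0, 1]")


@dataclass
class ImageStats:
    """Per-pixel statistics over a frame stack."""

    mean: np.ndarray
    std: np.ndarray
    snr: np.ndarray  # mean/std; +inf where std == 0 and mean > 0


def max_shot_noise_snr(saturation_flux_hz: float, pixel_rate_hz: float) -> float:
    """Shot-noise SNR of a pixel filled to the detector's rate limit:
    ``sqrt(saturation_flux / pixel_rate)``."""
    if not (saturation_flux_hz > 0 and pixel_rate_hz > 0):
        raise InputDomainError("saturation flux and pixel rate must be positive")
    return float(np.sqrt(saturation_flux_hz / pixel_rate_hz))


def pmt_snr(photons_per_pixel: float, pmt: PMTParams) -> float:
    """Shot-noise SNR with excess-noise penalty: ``sqrt(n / F)``."""
    if photons_per_pixel < 0:
        raise InputDomainError("photons_per_pixel must be >= 0")
    return float(np.sqrt(photons_per_pixel / pmt.excess_noise_factor))


def frames_to_match_snr(target_snr: float, single_frame_snr: float) -> float:
    """Frames to average so sqrt(N) scaling lifts ``single_frame_snr`` to
    ``target_snr``: ``(target/single)^2``, real-valued (caller rounds)."""
    if not (target_snr > 0 and single_frame_snr > 0):
        raise InputDomainError("SNR values must be positive")
    return (target_snr / single_frame_snr) ** 2


def resonant_pixel_rates(scan: ScanGeometry) -> tuple[float, float]:
    """(peak, average) pixel rates for a sinusoidal sweep.

    Average is ``line_rate * pixels_per_line``; the peak exceeds it by the
    sinusoidal velocity factor ``arcsin(ff)/ff`` for the digitized sweep
    fraction ``ff`` (pi/2 at ff=1, -> 1 as ff -> 0).
    """
    average = scan.line_rate_hz * scan.pixels_per_line
    ff = scan.fill_fraction
    peak = average * float(np.arcsin(ff) / ff)
    return peak, average


def sipm_pileup_transform(device: SiPMDeviceParams, dwell_s: float):
    """Per-pixel saturating transform for SiPM frame synthesis.

    Maps incident photons/pixel to expected detected photons/pixel using the
    renewal-theory charge yield of the Monte Carlo model: a cell hit at
    Poisson rate ``r`` yields a fraction ``1/(1 + r*tau_rc)`` of full-cell
    charge, with ``r = pde * flux / n_microcells``.
    """
    if not dwell_s > 0:
        raise InputDomainError("dwell_s must be > 0")

    def transform(photons_per_pixel: np.ndarray) -> np.ndarray:
        flux = photons_per_pixel / dwell_s
        r = device.pde * flux / device.n_microcells
        return device.pde * photons_per_pixel / (1.0 + r * device.tau_rc_s)

    return transform


def synthesize_frames(
    object_map: np.ndarray,
    photons_at_unit_brightness: float,
    n_frames: int,
    detector: str = "ideal",
    seed=None,
    *,
    pmt: PMTParams | None = None,
    device: SiPMDeviceParams | None = None,
    dwell_s: float | None = None,
) -> np.ndarray:
    """Poisson frame stack for a relative-brightness object map.

    detector:
      * ``"ideal"`` — pure Poisson counts;
      * ``"sipm"``  — mean photon count passed through the pile-up
        saturating transform (requires ``device`` and ``dwell_s``);
      * ``"pmt"``   — quantum-efficiency thinning, excess-noise variance
        inflation by ``F`` (Gaussian broadening of the Poisson counts), and
        clipping at ``saturation_flux * dwell`` (requires ``pmt`` and,
        for the clip, ``dwell_s``).

    Returns an array of shape ``(n_frames, *object_map.shape)``.
    """
    obj = np.asarray(object_map, dtype=np.float64)
    if np.any(obj < 0):
        raise InputDomainError("object_map brightness must be >= 0")
    if photons_at_unit_brightness < 0:
        raise InputDomainError("photons_at_unit_brightness must be >= 0")
    if n_frames < 1:
        raise InputDomainError("n_frames must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lam = obj * photons_at_unit_brightness
    if detector == "ideal":
        return rng.poisson(lam, size=(n_frames, *obj.shape)).astype(np.float64)
    if detector == "sipm":
        if device is None or dwell_s is None:
            raise InputDomainError("sipm detector requires device and dwell_s")
        lam_det = sipm_pileup_transform(device, dwell_s)(lam)
        return rng.poisson(lam_det, size=(n_frames, *obj.shape)).astype(np.float64)
    if detector == "pmt":
        if pmt is None:
            raise InputDomainError("pmt detector requires pmt params")
        lam_det = lam * pmt.quantum_efficiency
        counts = rng.poisson(lam_det, size=(n_frames, *obj.shape)).astype(np.float64)
        if pmt.excess_noise_factor > 1.0:
            counts += rng.standard_normal(counts.shape) * np.sqrt(
                (pmt.excess_noise_factor - 1.0) * lam_det
            )
            counts = np.maximum(counts, 0.0)
        if dwell_s is not None:
            counts = np.minimum(counts, pmt.saturation_flux_hz * dwell_s)
        return counts
    raise InputDomainError(f"unknown detector tag {detector!r}")


def per_pixel_snr(frame_stack: np.ndarray) -> ImageStats:
    """Mean/std/SNR per pixel over the stack (first) dimension.

    Pixels with zero temporal standard deviation get +inf SNR (flagging
    identical frames) or NaN when the mean is also zero.
    """
    stack = np.asarray(frame_stack, dtype=np.float64)
    if stack.ndim < 2 or stack.shape[0] < 2:
        raise InsufficientDataError("need a stack of >= 2 frames")
    mean = stack.mean(axis=0)
    std = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(std > 0, mean / std, np.where(mean > 0, np.inf, np.nan))
    return ImageStats(mean=mean, std=std, snr=snr)
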