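# sipmsim

Monte Carlo simulation and analysis toolkit for silicon-photomultiplier
(SiPM) detectors in high-speed point-scanning fluorescence microscopy.

Point-scanning two-photon microscopes are photon-starved at high frame
rates: a detector that saturates at `Φ_sat` photons/s imaging at `r`
pixels/s cannot exceed a shot-noise SNR of `sqrt(Φ_sat/r)` per frame. SiPMs
— arrays of tens of thousands of Geiger-mode avalanche microcells — push
that ceiling an order of magnitude past photomultiplier tubes, at the cost
of a new nonlinearity: each microcell recharges through its quench resistor
with time constant `τ_rc = Rq·Cj`, so photons that pile onto recharging
cells release only partial charge. This package provides the tools to
quantify that trade:

- **`sipmsim.montecarlo`** — exact event-driven simulation of a microcell
  array under Poisson illumination: PDE thinning, per-cell recharge
  `1 − e^(−Δt/τ_rc)`, 125 MHz sampled photocurrent traces, settling trims,
  pile-up saturation curves.
- **`sipmsim.ptc`** — photon-transfer-curve analysis: absolute flux from
  `mean²/variance · EB · fs`, gain from the variance-vs-mean slope,
  deviation-from-linear curves and the 10% saturation crossing.
- **`sipmsim.chain`** — two-exponential impulse response, current-domain
  pole-zero cancellation, Butterworth/brick-wall lowpass, equivalent
  bandwidth (`∫|H|²df / (fs/2)`), amplifier clipping, bias-supply droop.
- **`sipmsim.fluorophore`** — steady-state excitation under pulsed lasers:
  the pulse-train recursion, yield/power versus repetition rate, two-photon
  intensity-squared saturation, pulse-energy bookkeeping.
- **`sipmsim.imaging`** — resonant-scan pixel rates, synthetic Poisson
  frame stacks (ideal / SiPM pile-up / PMT excess-noise detectors),
  per-pixel SNR and frame-averaging equivalence.
- **`sipmsim.config` / `sipmsim.cli`** — validated YAML configs with
  unit-suffixed keys and a `sipmsim` command with `simulate-ptc`,
  `linearity`, `snr-plan`, `repetition-sweep`, `synth-frames` subcommands,
  each writing tabular output plus a reproducibility manifest.

See `docs/methods.md` for the model details and assumptions.

## Worked example

Validate the PTC flux formula against the simulator — launch a known
photon flux at a 14 400-cell device (τ_rc = 18 ns, PDE 0.4), record the
125 MHz trace, discard 50 recharge constants of settling, and read the flux
back from the sample statistics:

```python
import numpy as np
from sipmsim import SiPMDeviceParams, ptc_sweep, max_shot_noise_snr

dev = SiPMDeviceParams(n_microcells=14400, pde=0.4)   # reference profile
df = ptc_sweep(dev, [1e9], seed=42,
               min_samples=1_000_000, target_detected_events=1_000_000)
print(df[["sample_mean", "sample_variance", "estimated_flux_hz",
          "agreement_pct"]].to_string(index=False))
print("SNR ceiling at 2e9 photons/s, 10 MP/s:",
      round(max_shot_noise_snr(2e9, 1e7), 1))
```

```
 sample_mean  sample_variance  estimated_flux_hz  agreement_pct
   41.290998       531.208303       1.002988e+09      99.701155
SNR ceiling at 2e9 photons/s, 10 MP/s: 14.1
```

The estimator recovers the launched 10⁹ photons/s to 99.7% from nothing but
the trace mean and variance (41.3 DN mean, 531 DN² variance — note
`mean²/variance × fs / PDE ≈ 1.003×10⁹`), and the closed-form ceiling shows
why a 2×10⁹ photons/s detector at 10 MP/s is limited to single-frame
SNR 14.1.

The same pipeline from the shell:

```sh
sipmsim simulate-ptc --config run.yaml --out-dir results/
sipmsim repetition-sweep --config run.yaml --out-dir results/
```

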