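# Methods

`sipmsim` models the photon-detection physics of silicon-photomultiplier
(SiPM) detectors for high-speed point-scanning fluorescence microscopy, plus
the surrounding bookkeeping: the analog readout chain, photon-transfer-curve
(PTC) flux estimation, fluorophore excitation kinetics under pulsed lasers,
and shot-noise SNR accounting for scanned imaging.

## Monte Carlo microcell model

A SiPM is an array of `N` Geiger-mode avalanche photodiodes (microcells),
each quenched by a series resistor `Rq` and recharging through it with time
constant `τ_rc = Rq·Cj`. The simulation is event-driven and exact:

1. **Arrivals.** Launched photons are a homogeneous Poisson process of rate
   `Φ` over the run duration. Each photon survives thinning with probability
   PDE (photon detection efficiency), *before* cell assignment; survivors
   land on microcells drawn from the illumination profile (uniform by
   default, arbitrary nonnegative weights supported). An optional dark-count
   Poisson process (default rate 0) adds unthinned events. Optical crosstalk
   and afterpulsing are not modeled.
2. **Avalanches.** A cell's charge state recovers as `1 − e^(−Δt/τ_rc)`
   since its last avalanche. A photon on a cell in state `c` releases charge
   `c · g` (with `g` the single-cell gain) and resets that cell's recharge
   clock to zero — a Geiger discharge empties the cell regardless of how
   full it was. A never-fired cell is fully charged and releases exactly
   `g`, so total released charge is bounded by `n_detected · g` with
   equality only in the dilute limit.
3. **Sampling.** Released charge is accumulated wholly into the digitizer
   sample bin containing the arrival time (125 MHz default, no sub-sample
   interpolation). This keeps charge conservation exact and makes the
   binning an ideal integrate-and-dump whose equivalent bandwidth is
   exactly 1.

The implementation is vectorized: events are sorted per cell, inter-arrival
gaps give the charge factors in closed form, and a weighted bincount builds
the trace. One seeded NumPy generator drives each run; identical
(parameters, seed) reproduce traces bit-for-bit.

**Settling.** All cells start fully charged (as after a dark interval), so
the leading portion of a step-illumination trace is biased *high* relative
to the stationary state. `trim_settling` discards the first 50 recharge time
constants by default; after the trim the mean matches the renewal-theory
steady state `Φ_det·g/(1 + r·τ_rc)` per unit time (`r` the per-cell detected
rate) within Monte Carlo error.

**Reference device.** The bundled profile (14 400 microcells, Rq = 150 kΩ,
Cj = 0.12 pF → τ_rc = 18 ns, PDE 0.4, gain 12.9 DN/photon, 7 V overvoltage)
describes a representative 3 mm / 25 µm-pitch device. Cell count and RC
values are datasheet-order estimates for that device class — not measured —
and are required config fields precisely so users substitute their own.

## PTC flux estimation

For Poisson-limited samples, `photons/s = mean²/variance · EB · fs`, where
`EB` is the equivalent bandwidth of everything between photocurrent and
digitizer and `fs` the sampling rate. Key properties, all tested:

- the estimate is exactly invariant under positive rescaling of the trace
  (no gain calibration needed);
- the variance uses the unbiased (n−1) estimator;
- a constant trace is rejected (zero variance carries no information);
- the slope of variance against mean across an illumination sweep equals
  `gain · EB`, so `estimate_gain` returns `slope/EB`.

The formula yields the *detected* flux; `ptc_sweep` divides by the PDE to
report launched-equivalent flux (thinning of a Poisson process is exact
scaling). Per-point durations are chosen to give at least 2×10⁶ post-trim
samples *and* an expected 2×10⁶ detected events, equalizing the relative
statistical error (~0.1–0.2%) across flux decades; with the reference
device, agreement with the launched flux exceeds 99.5% at every point of a
1e8–1e10 photons/s grid.

**Linearity curves.** Under pile-up the mean²/variance estimate is *not*
monotone (the variance collapses faster than the mean squared, and the
estimate overshoots beyond per-cell occupancy `r·τ_rc ≈ 1`). Saturation
curves therefore use the variance alone converted to photons/s through the
known gain (`estimated_flux_from_variance_hz`), which falls monotonically
with pile-up. The linear reference slope is a through-origin fit over the
lowest decade of the grid (configurable), and the 10% crossing is
interpolated linearly in log-flux, where the curves are smooth.

## Analog chain

The single-photon response is `A_f e^(−t/τ_f) + A_s e^(−t/τ_s)`: a fast
sub-nanosecond component (array capacitance discharging) and a slow
component at the recharge time constant carrying ~10× the charge.
Amplitudes follow from the charge split `A_sτ_s : A_fτ_f = ratio : 1` and
total integral = gain. Time-constant defaults (0.8 ns / 18 ns) are
representative, not measured.

**Pole-zero cancellation** is the rational filter
`H(s) = a(τ_z s + 1)/(a τ_z s + 1)`: unity gain at high frequency, DC gain
`a`, zero at `1/τ_z`. With `τ_z` matched to the slow pole the slow
exponential is replaced by a residual decaying with `a·τ_z`; mismatched
zeros leave a slow residue whose amplitude follows the partial-fraction
expansion (tested symbolically). Discretization uses the bilinear
transform; the residual slow-pole leakage from frequency warping is far
below 1% of the slow-component energy on 125 MHz grids. Performing this
cancellation *before* amplification is what buys dynamic range: with the
divider attenuation set to the fast-charge fraction (1/11 at ratio 10), the
amplifier sees ~11× less steady-state signal per photon, so matched rails
clip at roughly an order of magnitude higher flux than a chain that
amplifies the full two-exponential response first.

**Lowpass.** The bandwidth-matching filter defaults to a causal 4th-order
Butterworth (the filter family is a config choice; an ideal brick-wall
variant exists for analytic tests). **Equivalent bandwidth** is
`∫|H|² df / (fs/2)` by trapezoid integration on the caller's grid; the
brick-wall constructor duplicates the cutoff point so the discontinuity
integrates exactly (25 MHz at 125 MHz sampling → exactly 0.4). Parseval
consistency — filtered/unfiltered white-noise variance equals the
equivalent bandwidth — holds within 2% on 10⁶-sample traces.

**Bias droop** (optional, off unless a supply section is configured) scales
the effective overvoltage by `1/(1 + max(0, I/I_max − 1))`: unity through
the knee at the supply's current limit, smooth hyperbolic roll-off beyond.
This is a deliberately simple stand-in for a current-limited generator's
gradual voltage drop; nothing in the package calibrates it to a specific
supply.

## Fluorophore kinetics

With post-pulse excited fraction `x`, per-pulse excitation probability `p`,
period `T = 1/R` and lifetime `τ`, one period gives
`x' = x·e^(−T/τ) + p(1 − x·e^(−T/τ))`. The recursion is affine, so the
fixed point `x* = p/(1 − (1−p)e^(−T/τ))` is exact — the 10⁴-pulse iteration
survives only as an independent oracle in the tests. Yield per fluorophore
per second is `R·x*·(1 − e^(−T/τ))`.

The "10% excited" operating point is ambiguous; three conventions are
implemented and selectable:

- `per_pulse` (p = 0.1), `post_pulse` (x* = 0.1, the default), and
  `time_averaged`. The default gives the best qualitative match to the
  expected behavior of short-lifetime dyes (≈3.3× yield at 4× rate for
  ≈3.8× power). Under `time_averaged` the yield is exactly
  `target/τ` at every repetition rate — a closed form showing that
  convention cannot produce any rate dependence, which is why it is not
  the default.

Two-photon bookkeeping: per-pulse excitation scales as pulse energy squared
at fixed pulse width, so required pulse energy ~ `sqrt(p)` and average
power ~ `R·sqrt(p)`; sweeps are normalized to 78 MHz (the standard
Ti:Sapphire rate). Saturation detection fits the squared law on the lowest
power decade and flags the first >10% deviation, interpolated in log-power.
Triplet states and photobleaching are out of scope.

## Imaging SNR

Per-pixel SNR is mean/std across sequential frames. The closed forms —
`sqrt(Φ_sat/r)` for the saturation-limited ceiling, `sqrt(n/F)` with excess
noise, `(target/single)²` frames to match — are one-liners kept as named,
tested operations because they anchor the design space. Resonant-scan
rates: average = line rate × pixels/line; peak exceeds it by the sinusoidal
velocity factor `arcsin(ff)/ff` for a digitized amplitude fraction `ff`
(π/2 for the full sweep, →1 as ff→0). Frame synthesis draws per-pixel
Poisson counts; the SiPM tag saturates the mean through the renewal-theory
yield `1/(1 + r·τ_rc)` (the same closed form the Monte Carlo reproduces),
and the PMT tag inflates variance by `F` via Gaussian broadening and clips
at saturation flux × dwell. `F` deliberately has no default — it depends on
tube and gain and must be supplied.

## Problem sizes and numerical choices

- PTC validation sweeps use 2×10⁶ samples / 2×10⁶ expected events per flux
  point (the package's chosen operating point for ~0.1% statistical error);
  the test suite runs reduced grids with the same rule.
- Monte Carlo memory scales with event count (~7 arrays of n_events);
  event-targeted durations keep the largest points near 6×10⁷ events.
- Equivalent-bandwidth integration is trapezoid on the provided grid; grid
  density is the caller's responsibility (constructors default to ≥4097
  points).
- The fixed-point solver tolerance question is moot (closed form); all
  hypothesis-based property tests are seeded/derandomized.

## What the generator does and does not emulate

The Monte Carlo *is* the synthetic-data source: Poisson statistics, PDE
thinning, per-cell recharge pile-up, illumination inhomogeneity and dark
counts are faithful. It does not model amplifier noise, temperature/gain
drift, optical crosstalk, afterpulsing, bias-generator ringing, or
SPICE-level circuit behavior — so passing tests validate the counting
physics and estimator algebra, not a specific hardware build. Bench-derived
anchors (12.9 DN/photon gain, 5.97 DN dark noise, ~0.4 equivalent
bandwidth) are carried as reference constants, not re-derived.
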