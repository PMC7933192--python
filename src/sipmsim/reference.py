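"""Reference device profiles and measured benchmark constants.

The example device profile approximates a 3 mm, 25 um-pitch SiPM
(Hamamatsu S14420-3025 class).  The microcell count, quench resistance and
junction capacitance are *datasheet-derived order-of-magnitude estimates*
for this device class, not measured or manufacturer-printed values; treat
them as a documented starting point and substitute measured parameters for
quantitative work with real hardware.

``MEASURED`` collects bench-measured reference numbers for one detector
build (gain and dark-frame noise at 7 V overvoltage).  They are useful as
defaults and sanity anchors; they cannot be re-derived by simulation.
"""

from __future__ import annotations

from .chain import BiasSupplyParams, ImpulseResponseParams
from .montecarlo import SiPMDeviceParams

# 3 mm / 25 um pitch -> 120 x 120 = 14400 microcells; Rq ~ 150 kOhm and
# Cj ~ 0.12 pF give tau_rc = 18 ns, in the tens-of-ns recharge regime.
EXAMPLE_DEVICE = SiPMDeviceParams(
    n_microcells=14400,
    quench_resistance_ohm=150e3,
    junction_capacitance_f=0.12e-12,
    pde=0.4,
    single_cell_gain=12.9,
    overvoltage_v=7.0,
)

EXAMPLE_IMPULSE = ImpulseResponseParams(
    fast_time_constant_s=0.8e-9,
    slow_time_constant_s=EXAMPLE_DEVICE.tau_rc_s,
    slow_to_fast_charge_ratio=10.0,
)

EXAMPLE_BIAS = BiasSupplyParams(max_current_a=10e-3, bias_voltage_v=50.0)

#: Bench-measured reference values at 7 V overvoltage.
MEASURED = {
    "gain_dn_per_photon": 12.9,
    "dark_frame_std_dn": 5.97,
    "equivalent_bandwidth": 0.4,  # with the 25 MHz lowpass at 125 MHz sampling
}


def dark_noise_photon_fraction(
    dark_frame_std_dn: float = MEASURED["dark_frame_std_dn"],
    gain_dn_per_photon: float = MEASURED["gain_dn_per_photon"],
) -> float:
    """Dark-frame noise expressed as a fraction of the single-photon
    amplitude (dark std / gain)."""
    if gain_dn_per_photon <= 0:
        raise ValueError("gain must be positive")
    return dark_frame_std_dn / gain_dn_per_photon
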