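"""Optical vs electrical dose-response: blink correction, Hill and Boltzmann.

The optical arm is an uncorrected P_L1 dose series (Hill curve with
EC50 = 0.33 uM plus the 12% dye-blink baseline and measurement noise); the
electrical arm is a -70 mV peak-current series with EC50 = 0.43 uM.  Both
are fitted with Hill curves after baseline subtraction/normalization, and a
conductance-voltage relation is fitted with a Boltzmann function.
"""

import numpy as np

import optogate as og

concs = np.array([0.01, 0.03, 0.1, 0.33, 1.0, 3.0, 10.0])

raw = og.simulate_dose_series(concs, ec50=0.33, hill_n=2.0, response_max=0.5,
                              baseline=0.12, noise_sd=0.05, seed=1)
raw = np.clip(raw, 0.0, 1.0)
corrected, floored = og.correct_blinking(raw, blink_fraction=og.BLINK_FRACTION)
normalized = og.normalize(corrected, corrected.max())
optical = og.fit_hill(concs, normalized)

current = og.simulate_dose_series(concs, ec50=0.43, hill_n=2.0,
                                  response_max=1.0, baseline=0.0,
                                  noise_sd=0.05, seed=2)
electrical = og.fit_hill(concs, current)

report = og.compare_optical_electrical(optical, electrical)
print(f"optical EC50    : {optical.ec50:.3f} uM (generated at 0.33)")
print(f"electrical EC50 : {electrical.ec50:.3f} uM (generated at 0.43)")
print(f"ratio, |diff|   : {report.ratio:.3f}, {report.difference:.3f} uM")
print(f"mismatch flag   : {report.mismatch} (disjoint 95% CIs would flag)")

volts = np.arange(-40.0, 201.0, 20.0)
table = og.simulate_gv_currents(volts, v_half=100.0, z_valence=1.0,
                                i_max=1.0, noise_sd=0.02, seed=3)
gv = og.fit_boltzmann(table["voltage_mV"], table["current"])
print(f"Boltzmann V0.5  : {gv.v_half:.1f} mV (generated at +100), "
      f"z = {gv.z_valence:.2f}")
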