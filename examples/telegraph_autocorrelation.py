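"""Stationary noise analysis of a simulated two-state fluorescence signal.

A symmetric telegraph switching at 58.8 1/s in each direction relaxes at
k01 + k10 = 117.6 1/s, so the autocovariance of its 500 Hz recording should
decay with tau = 1/117.6 = 8.5 ms.  We simulate 200 s, estimate the
normalized autocovariance, and fit a single exponential.
"""

import numpy as np

import optogate as og
from optogate.trace import FluorescenceTrace

path = og.simulate_telegraph(k01=58.8, k10=58.8, duration=200.0, seed=1)
trace = FluorescenceTrace(path.bin_average(0.002), dt=0.002)
lags, c = og.autocovariance(trace, max_lag=0.1)
fit = og.fit_exp_decay(lags, c, n_components=1)

print(f"occupancy of the bright state : {path.occupancy(1):.3f} (expect 0.5)")
print(f"fitted tau                    : {fit.taus[0]*1e3:.2f} ms (expect 8.5 ms)")
print(f"fit offset / residual         : {fit.offset:.4f} / {fit.fit_residual:.2e}")

# a second, slower process adds a second exponential component, the signature
# of agonist-stabilized bright bursts
slow = og.simulate_telegraph(6.757 / 2, 6.757 / 2, 200.0, seed=2)
mix = FluorescenceTrace(path.bin_average(0.002) + slow.bin_average(0.002),
                        dt=0.002)
lags2, c2 = og.autocovariance(mix, max_lag=1.0)
n, ratio = og.select_components(lags2, c2)
fit2 = og.fit_exp_decay(lags2, c2, n_components=2)
print(f"components preferred          : {n} (SSR ratio {ratio:.3g})")
print(f"two-component taus            : {fit2.taus[0]*1e3:.1f} ms, "
      f"{fit2.taus[1]*1e3:.0f} ms (expect 8.5 and 148)")
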