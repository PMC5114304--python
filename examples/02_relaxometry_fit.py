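"""Fit T2* from a simulated 4-echo GRE acquisition.

Simulates noisy mono-exponential echo decays at the default echo times
(2.53/7.03/12.55/20.35 ms), fits T2* and S0 per vertex by log-linear least
squares, and prints recovery accuracy and the weighted echo-ratio map.
"""

import numpy as np

import myelinmap as mm
from myelinmap.relaxometry import DEFAULT_ECHO_TIMES as TE

rng = np.random.default_rng(0)
n = 5000
true_t2s = rng.uniform(0.02, 0.05, size=(n, 1))   # s
true_s0 = rng.uniform(80, 120, size=(n, 1))       # a.u.

signal = true_s0 * np.exp(-TE[None, :] / true_t2s)
signal += 1.0 * rng.standard_normal(signal.shape)  # ~1% noise at echo 1

series = mm.EchoSeries(TE, signal)
fit = mm.fit_t2star(series)
t2sw = mm.t2star_weighted(series)

rel_err = np.abs(fit.t2star - true_t2s.ravel()) / true_t2s.ravel()
print(f"fitted {fit.fittable.sum()}/{n} vertices")
print(f"median |T2* error|: {100 * np.nanmedian(rel_err):.2f}%  "
      f"(per-vertex noise; the mean is unbiased to well under 2%)")
print(f"mean fitted T2*: {np.nanmean(fit.t2star):.4f} s "
      f"vs true mean {true_t2s.mean():.4f} s")
# T2*w = echo4/echo1 cancels the receive profile; for a noiseless decay it
# equals exp(-(TE4 - TE1)/T2*).
print(f"mean T2*w: {np.nanmean(t2sw):.4f} "
      f"(noiseless value at T2*=0.03 s: {np.exp(-(TE[-1]-TE[0])/0.03):.4f})")
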