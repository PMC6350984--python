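"""Yule-Walker fit and parametric spectrum of a known AR(1) process.

Simulates y[n] = 0.9 y[n-1] + e[n], recovers the coefficient by the
Yule-Walker method, and evaluates the closed-form spectral density
S(f) = 1/|1 + a exp(-j 2 pi f)|^2 at the band edges.
"""
import numpy as np

from artexus.armodel import ARModel, ar_spectrum, yule_walker

rng = np.random.default_rng(0)
n = 10_000
y = np.zeros(n)
e = rng.standard_normal(n)
for t in range(1, n):
    y[t] = 0.9 * y[t - 1] + e[t]

model = yule_walker(y, p=1)
print(f"true a1 = -0.900, estimated a1 = {model.coeffs[0]:.3f}, "
      f"noise variance = {model.noise_var:.3f}")

s = ar_spectrum(ARModel([-0.9], 1.0), n_freq=512)
print(f"S(0)   = {s.density[0]:.2f}   (closed form 1/(1-0.9)^2 = 100)")
print(f"S(0.5) = {s.density[-1]:.4f} (closed form 1/(1+0.9)^2 = 0.2770)")
print("\nA low-pass AR(1): energy piles up at DC and falls off toward Nyquist.")
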