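"""Wavelet band decomposition: where a tone's energy lands, and trend removal.

Feeds a low tone, a high tone and a slow ramp through the Daubechies
CWT band split and prints each band's share of the reconstructed energy.
"""
import numpy as np

from artexus.bands import get_bank
from artexus.config import WaveletConfig

bank = get_bank(WaveletConfig())
n = np.arange(400)

for label, x in [
    ("low tone  f=0.02", np.sin(2 * np.pi * 0.02 * n)),
    ("high tone f=0.40", np.sin(2 * np.pi * 0.40 * n)),
    ("slow ramp       ", np.linspace(0, 1, 400)),
]:
    bands = bank.band_signals(x)
    energies = {b: float((v ** 2).sum()) for b, v in bands.items()}
    total = energies["LF"] + energies["MF"] + energies["HF"]
    shares = {b: (energies[b] / total if total else 0.0) for b in ("LF", "MF", "HF")}
    print(f"{label}: LF {shares['LF']:.2f}  MF {shares['MF']:.2f}  "
          f"HF {shares['HF']:.2f}  TB-rms {np.sqrt((bands['TB']**2).mean()):.3f}")

print(
    "\nTones land in the band matching their frequency; the ramp's TB rms is\n"
    "near zero because the total band excludes the very-low-frequency trend\n"
    "scales — this is what makes the features robust to intensity inhomogeneity."
)
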