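"""Fit an MVAR model and derive PSD, coherence, and directed influence.

Simulates a 2-node system in which node A drives node B (coupling 0.4,
no reverse coupling), fits an order-6 MVAR, and prints the beta-band
spectral summaries. PDC should show the planted A->B asymmetry; MSC is
symmetric by construction and cannot.
"""

import numpy as np

from strokebeta import fit_mvar, spectra
from strokebeta.synthetic import base_coefficients, simulate_continuous

coeffs = base_coefficients(fs=250.0, n_roi=2, couplings={(1, 0): 0.4})
x = simulate_continuous(coeffs, np.ones((2, 20000)), seed=1)

model = fit_mvar(x[None], order=6, fs=250.0)
dec = spectra(model)
beta = (dec.freqs >= 13) & (dec.freqs <= 30)

print(f"beta-band PSD:  A = {dec.psd[beta, 0].mean():.3f}, "
      f"B = {dec.psd[beta, 1].mean():.3f}")
print(f"beta-band MSC(A,B)    = {dec.msc[beta, 0, 1].mean():.3f}")
print(f"beta-band PDC(A -> B) = {dec.pdc[beta, 1, 0].mean():.3f}")
print(f"beta-band PDC(B -> A) = {dec.pdc[beta, 0, 1].mean():.3f}")
print("\nThe driven node B carries more beta power (it receives A's "
      "oscillation on top of its own), MSC shows the coupling without "
      "direction, and PDC isolates the direction: the A->B value is "
      "large while B->A stays near zero.")
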