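"""Fit every model to one noisy synthetic voxel decay.

A CTRW decay at the published VETC-positive means is corrupted with 2%
Rician noise (with the protocol's per-b signal averaging) and then inverted
by each model; the table compares fitted parameters with the truth.
"""
import numpy as np

from vetcdiff import AcquisitionProtocol, ModelParams, fit_decay, signal

protocol = AcquisitionProtocol()
b = np.asarray(protocol.b_values)
rng = np.random.default_rng(7)

truth = ModelParams("CTRW", s0=1000.0,
                    values={"D": 1.27, "alpha": 0.91, "beta": 0.64})
clean = signal(truth, b)
sigma = 0.02 * truth.s0
noisy = np.array([
    np.mean(np.sqrt((clean[j] + rng.normal(0, sigma, n)) ** 2
                    + rng.normal(0, sigma, n) ** 2))
    for j, n in enumerate(protocol.averages)
])

print("true CTRW: D=1.27 alpha=0.91 beta=0.64, s0=1000, 2% Rician noise\n")
for model in ("MONO", "DKI", "SEM", "FROC", "CTRW"):
    fr = fit_decay(model, b, noisy, protocol)
    est = ", ".join(f"{k}={v:.3f}" for k, v in fr.markers().items())
    print(f"{model:5s} {est:55s} sse={fr.residual_sse:9.1f}")
print("\nEach model returns its own effective parameters for the same noisy"
      "\ncurve (ADC uses only the b<=1000 subset; FROC_mu is reported at the"
      "\nridge convention). Diffusivities are stable at 2% noise, while the"
      "\nheterogeneity exponents (alpha, beta, K) are visibly noise-sensitive"
      "\nwith a single 6-point decay — which is why the study averages over"
      "\nwhole-tumor VOIs.")
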