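"""Evaluate the five diffusion signal models on the study's b-value grid.

Parameters are the published VETC-positive group means; the printed table
shows how strongly each model's high-b tail deviates from the Gaussian
(monoexponential) decay.
"""
import numpy as np

from vetcdiff import AcquisitionProtocol, ModelParams, signal

protocol = AcquisitionProtocol()
b = np.asarray(protocol.b_values)

models = {
    "MONO": ModelParams("MONO", s0=1.0, values={"ADC": 1.03}),
    "DKI": ModelParams("DKI", s0=1.0, values={"D": 1.49, "K": 0.61}),
    "SEM": ModelParams("SEM", s0=1.0, values={"DDC": 1.51, "alpha": 0.58}),
    "FROC": ModelParams("FROC", s0=1.0, values={"D": 0.99, "beta": 0.66,
                                                "mu": 3.66}),
    "CTRW": ModelParams("CTRW", s0=1.0, values={"D": 1.27, "alpha": 0.91,
                                                "beta": 0.64}),
}

print("S(b)/S0 at b =", b.astype(int).tolist(), "s/mm^2")
for name, params in models.items():
    sig = signal(params, b, protocol.timing)
    print(f"{name:5s}", "  ".join(f"{v:.4f}" for v in sig))
print("\nAt b = 3000 the non-Gaussian models retain 2-4x more signal than the"
      "\nmonoexponential extrapolation — the high-b tail that encodes tissue"
      "\nheterogeneity.")
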