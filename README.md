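# vetcdiff

Non-Gaussian diffusion-weighted MRI modelling and biomarker statistics for
preoperative prediction of **vessels encapsulating tumor clusters (VETC)** in
hepatocellular carcinoma.

VETC is a vascular pattern in which CD34-positive, sinusoid-like vessels form
web-like networks around tumor clusters; it drives metastasis but is only
visible in resected tissue. `vetcdiff` implements the full quantitative chain
of a pilot study that asked whether multi-b-value DWI can predict VETC status
before surgery: five diffusion signal models fitted to 6-b-value decays
(b = 0, 200, 600, 1000, 2000, 3000 s/mm², with 1/1/1/2/4/6 averages), VOI
summaries and two-rater agreement, and the downstream biomarker statistics
(group tests, logistic combination, ROC/Youden, DeLong). Because the patient
images are not public, the package ships a first-class synthetic-cohort and
phantom generator whose defaults are the study's published group
distributions (46 VETC-negative vs 40 VETC-positive patients).

## The models

With `b' = b/1000` (ms/μm²) so that diffusivities are in μm²/ms:

| model | signal equation | parameters |
|---|---|---|
| MONO | S = S₀·exp(−b′·ADC) | ADC |
| DKI  | S = S₀·exp(−b′D + b′²D²K/6) | D, K |
| SEM  | S = S₀·exp[−(b′·DDC)^α] | DDC, α |
| FROC | S = S₀·exp[−D·μ^{2(β−1)}·(γG_dδ)^{2β}·(Δ − (2β−1)/(2β+1)·δ)] | D, β, μ |
| CTRW | S = S₀·E_α[−(b′D)^β] | D, α, β |

E_α is the one-parameter Mittag-Leffler function
E_α(z) = Σ_k z^k/Γ(αk+1), evaluated here to ≤1e-8 absolute accuracy on the
negative real axis by a conditioned power series, a deterministic
Gauss-Legendre evaluation of Pollard's complete-monotonicity integral, and
an adaptive fallback (`vetcdiff.mittag_leffler`). For FROC, the gradient
amplitude G_d is back-solved per b from b = (γG_dδ)²(Δ − δ/3); the timing
defaults (δ = 15 ms, Δ = 30 ms, γ = 267.513 rad·ms⁻¹·mT⁻¹) are explicit and
overridable.

Fitting is bounded trust-region nonlinear least squares with deterministic
multi-starts (plus a profiled coarse-grid search for the non-convex CTRW
objective), residuals weighted by the per-b number of averages, and ADC
restricted to the b = 0/600/1000 subset, mirroring the study protocol.

## Worked example

```bash
python examples/04_cohort_statistics.py
```

prints (seed 42):

```
ADC        t_test       p=0.3235  neg 1.06±0.14  pos 1.02±0.18
DKI_K      t_test       p=0.0000  neg 0.53±0.07  pos 0.62±0.08  AUC=0.792 cutoff=0.575 youden=0.492
CTRW_alpha t_test       p=0.0006  neg 0.87±0.06  pos 0.91±0.04  AUC=0.702 cutoff=0.870 youden=0.397
```

The two markers that genuinely separate the simulated groups are the
kurtosis DKI_K and the CTRW temporal heterogeneity exponent CTRW_α —
exactly the study's finding — while ADC does not; their empirical AUCs and
Youden-optimal cutoffs land near the published values (AUC 0.678 at cutoff
0.557 for DKI_K; 0.672 at 0.854 for CTRW_α). `examples/05_full_study.py`
runs the same chain end-to-end (screening arithmetic 159 → 86, ICC per
marker, significance gate, logistic combination, DeLong matrix) and writes
the report tables as CSV.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the empirical AUC of each discriminating marker
when patient values are simulated from the published group distributions
(500 replicate cohorts of 46 + 40; the mean AUC over replicates is
reported), using the package's own samplers and ROC machinery.
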