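# ivimkurt

Quantitative diffusion-weighted MRI (DWI) analysis of focal prostate
lesions with the combined **IVIM-kurtosis** model and the two-point
**monoexponential** (ADC) model — from raw multi-b-value volumes to the
full diagnostic-statistics report.

The package is aimed at quantitative-imaging researchers who want a tested,
reproducible reference pipeline for this family of analyses: voxel-wise
model inversion, first-order histogram radiomics per ROI, and the standard
two-class diagnostic battery (gated group tests, observer ICC, ROC with
Youden cutoffs and exact CIs, Spearman correlation against Gleason score,
logistic combined models, DeLong comparison of correlated AUCs). Because
clinical DWI cohorts of this kind are rarely shared, the package also ships
a first-class synthetic-data generator that emulates a 20 + 20 lesion
study — cancer-like vs. benign hyperplasia/prostatitis-like — with
published per-class parameter distributions, Rician noise and per-b-value
averaging.

## Models

For diffusion weighting b (s/mm²) the IVIM-kurtosis signal model is

    S(b)/S₀ = f·exp(−b·D*) + (1 − f)·exp(−b·D + (b·D)²·K/6)

with tissue diffusion coefficient D, pseudodiffusion coefficient D*,
perfusion fraction f and kurtosis parameter K. Voxel-wise maps of
(D, D*, f, K) are obtained by bound-constrained nonlinear least squares
over the nine-point scheme b = 0, 20, 50, 100, 200, 500, 1000, 1500,
2000 s/mm² (NEX 2, 2, 2, 2, 2, 3, 4, 6, 6), with variable-projection
multistart and a deterministic exact-fit escalation for noiseless data.
The monoexponential model S(b) = S₀·e^(−b·ADC) is inverted exactly from
the b = 50 and b = 1500 s/mm² volumes. Tables report D, D* and ADC in
×10⁻³ mm²/s.

## Worked example

Fit one noisy voxel generated at a known truth
(D = 0.85·10⁻³ mm²/s, D* = 8·10⁻³ mm²/s, f = 0.20, K = 1.4, SNR 50):

```python
import numpy as np
from ivimkurt import (DEFAULT_SCHEME, DiffusionParams, IVIMKurtosisModel,
                      add_rician_noise, ivim_kurtosis_signal)

truth = DiffusionParams(D=0.85e-3, Dstar=8e-3, f=0.2, K=1.4)
rng = np.random.default_rng(0)
clean = np.asarray(ivim_kurtosis_signal(DEFAULT_SCHEME.b, truth))
noisy = np.array([add_rician_noise(clean[i], 0.02, DEFAULT_SCHEME.nex[i], rng)
                  for i in range(len(DEFAULT_SCHEME))])

res = IVIMKurtosisModel.from_signals(noisy, DEFAULT_SCHEME.bvalues, DEFAULT_SCHEME.nex).fit()
print(res.summary())
```

```
IVIM-kurtosis voxel-wise fit
============================================================
voxels converged: 1   excluded: 0   failed: 0
S0 handling: fixed-to-b0   multistart: 6
------------------------------------------------------------
     D: mean   0.9828  sd      nan  range [0.9828, 0.9828] x1e-3 mm^2/s
 Dstar: mean  13.9103  sd      nan  range [13.9103, 13.9103] x1e-3 mm^2/s
     f: mean   0.1550  sd      nan  range [0.1550, 0.1550]
     K: mean   1.4793  sd      nan  range [1.4793, 1.4793]
```

D and K land close to the truth; f and D* wander further — at this scheme
and SNR the perfusion compartment of a single voxel is only weakly
identifiable (see `docs/methods.md`), which is why the pipeline aggregates
over ROIs before any statistics.

Run the full synthetic study end to end (generate, fit, summarize, test,
report):

```python
from ivimkurt import PhantomSpec, RunConfig, run_pipeline

bundle = run_pipeline(RunConfig(phantom=PhantomSpec(), seed=0))
bundle.write("out/")
```

Headline rows from `out/group_comparison.csv` and `out/roc.csv` at seed 0:

```
feature    test      statistic  p          direction
D_mean     pooled-t  -4.95      1.6e-05    lower in PCa
ADC_mean   pooled-t  -22.47     1.5e-23    lower in PCa
K_mean     pooled-t   2.54      1.5e-02    higher in PCa

name                  auc    auc_ci          sens%  spec%  youden  criterion
IVIM-kurtosis model   1.000  (0.912–1.000)   100.0  100.0  1.00    >0
ADC/MEM model         1.000  (0.912–1.000)   100.0  100.0  1.00    >0
```

Both combined models separate the synthetic classes perfectly, so their
DeLong comparison is degenerate (z = 0, p = 1) and reported as such. The
`ivimkurt` console script exposes the same stages as subcommands
(`phantom`, `fit`, `summarize`, `stats`, `run`) with `--config`, `--seed`
and `--out` flags.

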