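# Methods

## Scope and models

`ivimkurt` implements a complete diffusion-weighted MRI (DWI) analysis of
focal prostate lesions built around two signal representations fitted to
multi-b-value acquisitions:

* the **IVIM-kurtosis model**, a hybrid of intravoxel incoherent motion and
  diffusion-kurtosis imaging,

  S(b)/S₀ = f·exp(−b·D*) + (1 − f)·exp(−b·D + (b·D)²·K/6),

  with tissue diffusion coefficient D (mm²/s), pseudodiffusion coefficient
  D* (mm²/s), perfusion fraction f ∈ [0, 1] and kurtosis parameter K ≥ 0;

* the **monoexponential model** S(b) = S₀·exp(−b·ADC), evaluated in its exact
  two-point form on the b = 50 and b = 1500 s/mm² volumes.

The default acquisition scheme is the nine-point prostate protocol
b = 0, 20, 50, 100, 200, 500, 1000, 1500, 2000 s/mm² with per-b-value
averaging NEX = 2, 2, 2, 2, 2, 3, 4, 6, 6. Diffusion coefficients are carried
internally in mm²/s; all report tables display D, D* and ADC ×10³
("×10⁻³ mm²/s"), which keeps fitting and reporting units from mixing.

Downstream of the fits, the pipeline computes first-order histogram features
per lesion ROI, gated two-group tests, simulated-observer ICCs, Spearman
correlations against Gleason score, per-feature ROC analyses, logistic
combined models and a DeLong comparison of the combined-model AUCs.

## Synthetic-data generator

The phantom emulates the study design the statistics assume: 40 box-shaped
lesions (20 cancer-like "PCa", 20 benign "BPH/prostatitis") placed without
overlap in a 64 × 64 × 5 volume, each a single-slice 5 × 5 ROI (the analysis
convention is single-slice ROI drawing), surrounded by a fixed benign-like
background that is never analysed.

Per-voxel truth parameters are drawn independently per parameter from
truncated normal distributions whose means and SDs are the published
per-class ROI summary values:

| class | D (×10⁻³) | D* (×10⁻³) | f | K |
|---|---|---|---|---|
| PCa | 0.85 ± 0.24 | 0.742 ± 0.560 | 0.229 ± 0.107 | 1.396 ± 0.654 |
| BPH/prostatitis | 1.34 ± 0.30 | 1.038 ± 0.964 | 0.246 ± 0.091 | 0.949 ± 0.341 |

Cancer lesions draw a Gleason score from the empirical cohort frequencies
(5× GS 6, 8× GS 7, 3× GS 8, 4× GS 9). An optional monotone coupling
(`gs_coupling`, default off) shifts lesion-level D down and f/K up with
(GS − 7) in units of half a class SD, so rank-correlation analyses have a
recoverable truth signal when needed.

**Truncation windows.** Draws are truncated to D ∈ [0.35, 4]·10⁻³ mm²/s,
D* ∈ [0.02·10⁻³, 0.1] mm²/s, f ∈ [0.01, 0.95], K ∈ [0.1, 10]. The upper
bounds simply keep draws physical; the lower floors are identifiability
guards derived from an explicit degeneracy analysis of the nine-point
scheme: as f → 0 or D* → 0 the perfusion compartment leaves no signature in
the signal; as D → 0 the entire decay disappears inside the sampled b-range;
and at K → 0 with D* ≈ D the two compartments become *exactly* exchangeable
(the likelihood is invariant under (D, D*, f) ↔ (D*, D, 1 − f)), so f is
unrecoverable in principle. The floors sit below the published per-class
10th percentiles (D: 0.47/0.70·10⁻³; K: 0.14/0.23), so the truncated
distributions still match the published mean ± SD summaries closely.

**Noise.** Magnitude (Rician) noise is generated per excitation —
sqrt((S + g₁)² + g₂²) with g₁, g₂ ~ N(0, σ²) — and averaged per b-value
according to the NEX scheme, mirroring scanner-side averaging. The default
σ = 0.02·S₀ corresponds to SNR 50 at b = 0 before averaging.

**What the phantom does not emulate.** Anatomically realistic geometry,
partial-volume effects, spatial noise correlation, motion/eddy artifacts,
within-lesion parameter correlation (only marginals are published), and the
two-level variance structure of real cohorts: per-voxel draws reuse the
*between-lesion* SDs, because no within-lesion variance is recoverable from
the published summaries. Lesion means are therefore tighter around the class
means than in the real cohort, and between-lesion group tests are more
powerful than the published ones. Passing pipeline tests consequently
demonstrate correctness of the machinery and of qualitative directions, not
clinical effect-size realism.

## Voxel-wise fitting

The estimator is bound-constrained nonlinear least squares of the
IVIM-kurtosis model jointly over all nine b-values, with S₀ fixed to the
mean of the b = 0 acquisitions (a "free S₀" mode exists). Default bounds:
D ∈ [0, 4·10⁻³], D* ∈ [0, 0.5] mm²/s, f ∈ [0, 1], K ∈ [0, 30] — wide enough
to represent the published percentile ranges; they are configuration, not
constants. No D* > D ordering constraint is imposed: the published
per-class D* summaries themselves lie below typical D values, so the
original analysis evidently did not enforce one.

The objective is multi-modal: a near-degenerate valley where the two
compartments exchange roles (D* ≈ D), and a trade-off where a slow
perfusion plateau mimics the kurtosis upturn. Three mechanisms address
this, all deterministic:

1. **Variable-projection start grid.** f enters the model linearly, so for
   every (D, D*, K) combination of a coarse grid the optimal f is closed
   form and the full coarse cost surface is evaluated vectorized. The best
   candidates, kept diverse across decades of D*, seed the trust-region
   polishes (default 6 starts; the 6th guards against coarse-grid ranking
   demoting the correct basin).
2. **Exact-fit escalation.** When the best residual is small enough to be
   consistent with noiseless data (cost ≤ 3·10⁻⁵ on the normalized signal)
   but above the exact-fit floor (10⁻²⁴), the fitter escalates: a
   compartment-swap start, a denser D* profile, a valley walk along the two
   flattest scaled-Jacobian singular directions, and seeded random
   restarts, all at machine tolerance. Across 4 000 noiseless draws from
   both class distributions (20 seeds × 100 voxels × 2 classes) this
   recovers every voxel within 1% (D, f, K) and 5% (D*).
3. **Batched map engine.** `fit_maps` defaults to a vectorized batched
   Levenberg–Marquardt over all voxels at once (box constraints through
   sigmoid transforms — log-scale for the rate parameters D and D*, linear
   for f and K; per-voxel damping), at about 1 ms/voxel. Voxels whose
   residual indicates noiseless data are automatically handed to the
   escalating per-voxel path, so noiseless maps are still exact. The
   per-voxel scipy path remains available as `engine="voxel"` and is the
   reference estimator for accuracy studies. Both engines are bit-
   reproducible; their noisy-data estimates agree in distribution (per-voxel
   minima along the degenerate valley can differ).

Voxels that are all-zero, negative-dominated, or below a configurable
high-b noise floor are excluded with an explicit status code — never
silent zeros; excluded map entries are NaN.

### Identifiability limits at realistic SNR

With truth drawn from the published class distributions, most voxels have
D* within a factor ~3 of D. On the nine-point scheme at SNR 50 the
per-voxel f is then statistically unidentifiable: fits *started at the
truth* migrate to genuinely lower-cost minima far away along the valley,
and since f can overshoot upward much further than downward, its median
signed relative bias is on the order of +100% regardless of optimizer
effort, noise-floor correction, or SNR up to ~200. D inherits part of this
drift (median ≈ −10%); K's median stays within a few percent but its error
distribution is heavy-tailed (roughly a quarter of voxels miss K by more
than 5 at SNR 50, many at the box bounds). This mirrors the published
repeatability evidence for this protocol — D* ICC rows of 0, f
inter-observer ICCs as low as 0.12, and within-ROI f 90th percentiles
(≈ 0.66) far above the ROI means (≈ 0.23). The acceptance suite asserts the
nominal noisy-recovery bounds and documents the measured shortfalls rather
than relaxing them; ROI-level and cohort-level statistics remain far better
behaved than single voxels because the wander partially averages out.

## Histogram features

Eight first-order features per (lesion, parameter): mean, 10th/25th/50th/
75th/90th percentiles, skewness, kurtosis. Percentiles use linear
interpolation at position 1 + q/100·(n − 1) on the sorted values; moments
are population (n-denominator) moments; kurtosis is the non-excess Pearson
form m₄/m₂² (normal → 3). The non-excess convention is pinned by the
published ADC ROI kurtosis values clustering near 3 on near-Gaussian data;
it is applied uniformly to all parameters. Excluded/failed voxels are
dropped with a logged count; a summary requires at least two distinct valid
values.

## Cohort statistics

* **Group comparison gate** (α = 0.05 for both gates): Shapiro–Wilk
  normality per group and mean-centred Levene homoscedasticity. Both normal
  and homoscedastic → pooled t; normal but heteroscedastic → Welch t;
  otherwise Wilcoxon rank-sum in the normal approximation with tie and
  continuity correction. The branch taken and gate p-values are always
  recorded. The Welch-vs-pooled distinction is empirically pinned by the
  published PSA row, whose printed P matches the Welch degrees of freedom
  and not the pooled ones.
* **No multiple-testing correction** by default, matching the original
  analysis across its ~45 comparisons; a Benjamini–Hochberg helper is
  provided for users.
* **ICC**: two-way ANOVA single-measure forms — absolute agreement
  (ICC(2,1)/ICC(A,1) formula, the same computational form under random- and
  mixed-effects readings; used for both intra- and inter-observer tables)
  and consistency (ICC(3,1)); F-based and Satterthwaite confidence
  intervals. Categories: poor < 0.40 ≤ fair < 0.60 ≤ good < 0.75 ≤
  excellent, boundaries belonging to the upper category. Missing cells are
  rejected, never imputed. Observer ROIs are simulated by seeded boundary
  jitter (in-plane for single-slice ROIs) constrained to ≥ 50% overlap.
* **Spearman vs Gleason score**: average ranks under ties, two-sided p via
  the t approximation, computed over the cancer lesions.

## Diagnostics

The empirical ROC is evaluated over all observed cutoffs; orientation
("≤" versus ">") is chosen so AUC ≥ 0.5 and is reported as the association
criterion. The operating point maximizes the Youden index J = se + sp − 1
(ties resolve toward higher specificity). The AUC interval uses the DeLong
placement-value variance; the degenerate AUC = 1 case falls back to an
exact binomial bound on the n₁ + n₂ correctly ordered lesions, which
reproduces the published "1.000 (0.912–1.000)" convention for a 20/20
cohort. Sensitivity and specificity carry Clopper–Pearson exact intervals,
which reproduce the published one-decimal CI values for the 20/20 and 18/20
operating points exactly.

Combined diagnostic models are unregularized maximum-likelihood logistic
regressions on internally standardized member features; fitted
probabilities are the scores and their ROC uses the ">" orientation. Model
membership defaults to the per-family significant features (D, D*, K
family models), the pooled significant IVIM-kurtosis features, and the
significant ADC features — membership is configuration because the original
report does not enumerate it. Perfect separation proceeds under capped
iterations with an explicit warning; correlated AUCs are compared with the
paired DeLong z test (two perfect models are flagged degenerate with z = 0,
p = 1).

## Reproducibility and problem sizes

Every stochastic stage (phantom, noise, observer jitter) derives
sub-generators from one seed via `numpy` seed sequences; identical
configuration and seed give byte-identical report files (tables carry the
seed and a config hash in a leading comment line). The validation studies
use: 100 voxels per class for noiseless recovery, 500 cancer-class voxels
at SNR 50 for noisy recovery, and 100 seeded replicates of the full default
phantom for the group-difference replication study; these sizes make the
whole suite run in a few minutes on one CPU while keeping the Monte-Carlo
error of each reported rate well below the margins being tested.

## Known limitations

* Per-voxel f (and to a lesser degree D and K tails) are not reliably
  estimable at this scheme/SNR for the published parameter regime — an
  identifiability property of the design, not an optimizer defect (see
  above).
* The 40 lesions are treated as independent although a real cohort may
  contribute two lesions per patient for some patients; the original
  analysis does the same, and this package reproduces it as-is.
* Combined models are fitted and evaluated on the same lesions (no
  cross-validation), again reproducing the original design; the AUC = 1
  results this produces should be read accordingly.
* The phantom's flat within-lesion variance model makes between-lesion
  tests more powerful than in real data; effect sizes in the report tables
  are not calibrated to the clinic.
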