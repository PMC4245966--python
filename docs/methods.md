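# Methods

## Model

Expression of gene *i* in sample *j* is modelled, after a moderated log
transform, as a linear combination of a gene baseline, effects of the
primary phenotype(s) `y`, effects of known adjustment variables `a`, and
effects of `Q` unknown sample-level artifacts `u`:

```
E[log(g_ij + c)] = b_0i + Σ_k b_ki y_kj + Σ_ℓ c_ℓi a_ℓj + Σ_q d_qi u_qj
```

Artifacts are identifiable only up to a linear transformation, and only a
linear transformation is needed: any covariate spanning the same sample
space as `u` removes the artifact component from a downstream linear
model. The estimation strategy is therefore spectral. If one knew the set
of genes with `b_i = 0` and `c_i = 0`, row-centering that submatrix leaves
`G = d u' + E`, and the top right singular vectors estimate `u`
consistently as the number of such genes grows. The three algorithms
differ only in how they approximate that subset:

- **supervised** — an annotated negative-control list defines it exactly
  (weights λ_i ∈ {0, 1}); the phenotype labels are never touched, which is
  what makes the method stable under phenotype–artifact confounding.
- **two_step** — candidate factors come from the SVD of the residuals of
  the full design; genes whose F-test against those factors survives
  Benjamini–Hochberg at 0.05 get λ = 1; one weighted extraction follows.
- **irw** — soft weights λ_i = (1 − lfdr(p_artifact,i)) · lfdr(p_primary,i)
  are re-estimated against the current factors for a fixed number of
  iterations (default 5; no convergence test, the iteration count is
  reported). p_artifact is the F-test of the factor block given the full
  design; p_primary is the F-test of the primary block given intercept +
  adjustments + current factors (the conditional form: the factors stand
  in for the artifacts when asking "does this gene track the phenotype?").

Weighted extraction always operates on the λ-scaled, row-centered
moderated-log data — not on residuals. Residual SVD is used only to
initialize irw and to detect genes in two_step. Surrogates are *not*
orthogonalized against the phenotype; the weighting, not orthogonality,
is what separates artifact from signal (forcing orthogonality is exactly
the failure mode of residual RUV under confounding).

Sign convention: each factor's largest-magnitude entry is positive. SVD
is otherwise sign-ambiguous and determinism matters for comparisons.

## Moderated log

Counts and FPKMs are non-negative and right-skewed with exact zeros, so
all estimation runs on `log(g + c)`, natural base, default `c = 1`
(implemented via `log1p` for precision at small counts). `c = 0` is
allowed only when every value is positive. The choice of `c` trades
moderation of low-count variance against compression; it is exposed as a
parameter and not otherwise optimized here. Estimating factors on the
log scale also puts them on the scale of standard GLM link functions, so
they can be used directly as covariates in count-likelihood DE models.

Low-count filtering keeps genes with value strictly greater than
`min_count` (default 5) in at least `min_samples` (default 2) samples —
the conventional pre-filter for this kind of analysis; it is idempotent
and applied before estimation when requested.

## Number of surrogate variables

Permutation parallel analysis: residualize against the full design,
compute normalized squared singular values `s_k²/Σ s²`, rebuild the same
statistics on `n_perm` (default 20) copies of the data with entries
permuted independently within each gene row, and count leading components
exceeding the 90th percentile (α = 0.10) of their null distribution,
stopping at the first failure. Note the operating characteristic this
implies: on pure-noise data the first component exceeds its own null
quantile with probability α, so the procedure returns 0 about 90% of the
time, not always. Supervised estimation runs the same procedure on the
control-gene submatrix against the null design.

## Local false discovery rate

The weighting needs P(null | p). We use a two-group mixture:
π₀ estimated by the 0.8-quantile rule `π₀ = min(1, mean(p > 0.8)/0.2)`;
the marginal density f(p) by a Gaussian KDE on the boundary-reflected
sample {−p, p, 2−p}; lfdr = π₀/f clipped to [0, 1] and made monotone in p
by isotonic regression. The KDE bandwidth uses Silverman's rule on the
robust scale of the *original* p-vector, `0.9·min(sd, IQR/1.34)·m^(−1/5)`
(floored at 1e−3): a global Scott bandwidth on the reflected sample
oversmooths the spike of small p-values that carries all the signal and
makes the weights needlessly conservative. Two consequences worth
knowing: an *isolated* small p-value among nulls cannot be recognized (its
local density is indistinguishable from uniform — weights are informative
only when an appreciable fraction of genes shares the artifact), and the
isotonic pooling near p = 0 keeps even very strong genes somewhat below
λ = 1. Degenerate inputs (all p equal) fall back to the uniform-density
convention lfdr = π₀. Fewer than 20 p-values is an error.

## Baselines

Each comparison estimator is defined by which matrix is decomposed, all
on the row-centered moderated-log scale:

| variant | decomposed matrix |
|---|---|
| pca | the full matrix |
| ruv_controls | the control-gene submatrix |
| ruv_empirical | the `empirical_fraction` (default 0.5) of genes with the largest primary-variable F-test p-values |
| ruv_residual | residuals of the full design |

These are deliberately simple spectral characterizations, not
re-implementations of the RUVSeq generalized-least-squares estimators;
they capture the qualitative behavior that matters for comparison:
ruv_controls coincides with supervised sva on a shared control set (the
zero-weighted rows of the weighted SVD contribute nothing, so both
decompose the same submatrix — R² = 1 exactly); ruv_residual factors are
orthogonal to the phenotype by construction and therefore lose exactly
the artifact component that is correlated with it under confounding;
ruv_empirical with fraction 1 degenerates to PCA. Empirical-control
selection screens on association with the *primary* variable — screening
on batch association is impossible since batch is the thing being
estimated.

## Simulator

Counts are drawn gene-wise from a negative binomial with mean
`μ_i · exp(b_i y_j + d_i u_j)` and variance `μ + φ μ²` (φ = 0 → Poisson).
`y` and `u` are balanced binary labels; the 2×2 cell count is chosen so
the achieved squared correlation matches the `design_r2` target exactly
when an integer table exists (within 0.02 otherwise it errors, reporting
the nearest achievable values — e.g. at n = 12 only r² ∈ {0, 0.11, 0.44,
1} exist, which is why confounded-scenario analyses here use n = 28 where
r² = 0.51 is achievable). Effects are natural-log-scale Normal draws on
random gene subsets with exact bookkeeping; negative controls are drawn
from the batch-affected, non-DE genes and always carry a nonzero batch
coefficient.

Baseline (μ_i, φ_i) pairs can be estimated from any real count matrix by
method of moments (μ̂ = mean, φ̂ = max(0, (s² − μ̂)/μ̂²), zero-mean genes
dropped with a count), or drawn from built-in synthetic defaults
μ_i ~ LogNormal(log 250, 1), φ_i ~ LogNormal(log 0.1, 0.5) — orders of
magnitude typical of bulk RNA-seq.

Default study conditions: m = 1000 genes, n = 12 samples, 30% of genes
with a group effect and 30% with a batch effect (SD 1.0 each on the log
scale), 100 negative controls, orthogonal design. The two effect classes
are given comparable total signal deliberately: that is the regime in
which the methods genuinely differ — the leading principal component then
estimates a mixture of group and batch rather than collapsing onto either,
which is the situation that motivates weighting in the first place. The
simulator emulates gene-level NB counts only: no library-size variation,
GC/length bias, read-level error or correlated gene modules. Passing
tests therefore demonstrate correct behavior under the model's own
assumptions, not robustness to everything real data does.

## Differential expression and evaluation

DE is per-gene least squares of `log(g + 1)` on intercept + phenotype +
adjustment covariates with plain two-sided t-tests at the model's
residual df, optionally precision-weighted. Weights follow the voom idea:
lowess (span 0.5) of √(residual SD) against mean log-count, each
observation weighted by 1/trend(fitted)⁴ with the trend held flat beyond
the observed range. Empirical-Bayes variance shrinkage is intentionally
omitted: all comparisons here are rank-based and equal-df shrinkage
preserves ranks; this is the main simplification relative to a full
limma/voom stack. Genes whose residual variance sits at double-precision
noise are flagged and assigned p = 1. Multiple testing is
Benjamini–Hochberg (step-up running minimum, clipped at 1).

Rankings for concordance-at-the-top curves sort by ascending p, then
descending |t|, then gene id — fully deterministic. CAT(k) =
|top_k(A) ∩ top_k(B)|/k. Factor–truth association is squared Pearson
correlation for numeric truth and one-way ANOVA
F = [(RSS₀ − RSS₁)/(K−1)]/[RSS₁/(n−K)] for categorical truth (lab,
study). Calibration reports the empirical rejection rate at α and the
one-sample KS distance from Uniform(0, 1).

## Problem sizes

Simulation-backed checks use m = 1000 × n = 12 (n = 28 confounded) with
20-seed medians, and n = 200 samples for the mean–variance fidelity
check; these sizes make every qualitative comparison stable without
heroic compute. All randomness flows through explicit integer seeds;
repeated runs are bit-identical.

## Known limitations

- Weights are only as good as the lfdr estimate; with very few genes
  (< 20 p-values) or an artifact shared by only a handful of genes, the
  empirical modes are uninformative (use supervised mode).
- The number-of-factors rule tests leading components sequentially; a
  weak second factor hiding behind a strong first one can be missed.
- `ruv_*` baselines are spectral simplifications (see above).
- FPKM input is accepted anywhere counts are; the NB simulator, however,
  generates counts only.
- `SVA.transform` removes surrogate structure from the data it was fit
  on; surrogates are sample-specific, so there is no out-of-sample
  transform.
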