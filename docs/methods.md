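# Methods

## Model and test statistic

`kfdiff` compares the distributions of two (or more) groups of cells
from their expression profiles without assuming a parametric model.
Each cell's profile Y is embedded into a reproducing kernel Hilbert
space by the feature map φ of a chosen kernel, k(Y, Y′) = ⟨φ(Y),
φ(Y′)⟩.  Equality of distributions is tested through the kernel mean
embeddings μᵢ = E[φ(Y) | group i]: for a universal kernel such as the
Gaussian one, μ₁ = μ₂ is equivalent to equality of the underlying
distributions.

The unstandardized distance between embeddings is the (plug-in) MMD²,
mean(K₁₁) + mean(K₂₂) − 2·mean(K₁₂).  The headline statistic
standardizes this difference by the pooled within-group covariance
operator Σ_W = (n₁/n)Σ₁ + (n₂/n)Σ₂, truncated to its top-T spectral
directions:

    D̂²_T = (n₁n₂/n) ‖Σ̂_{W,T}^{−1/2} (μ̂₂ − μ̂₁)‖²
         = (n₁n₂/n) Σ_{t≤T} ⟨ê_t, μ̂₂ − μ̂₁⟩² / λ̂_t.

All covariance estimators are the biased (1/nᵢ) plug-in versions, so
the linear-kernel case reduces *exactly* to Hotelling's two-sample T²
with the biased pooled covariance (the test suite asserts this to
1e-8).  Under H₀, D̂²_T is asymptotically χ²(T); the asymptotic p-value
is the default for n ≥ 100 and a label-permutation p-value
(1 + b)/(B + 1) is available below that (and generally).

Truncation is the regularizer: ridge regularization of Σ̂_W is
deliberately not offered because it destroys the χ² null.  T defaults
to 4 for gene-wise (univariate) tests and 10 for whole-transcriptome
(multivariate) tests.

### Dual (Gram-space) computation

Nothing is ever computed in feature space.  With P the block-diagonal
per-group centering projector, the nonzero spectrum of Σ̂_W equals that
of (1/n)·PKP; eigenfunctions are recovered through dual coefficients
a_t = u_t/√(nλ_t), and every inner product (⟨ê_t, μ̂₂ − μ̂₁⟩, projection
scores, batch corrections) is a contraction of Gram rows.  Above
n ≈ 450 (and inside the permutation loop above n = 150) the top-T
eigenpairs come from a Lanczos solver with a fixed deterministic start
vector; below, from a full dense eigendecomposition.  Eigenvalues below
1e-12·λ₁ are treated as numerical zeros; a requested T above the
effective rank is capped with a warning, never an error.  Eigenvector
sign is fixed by making each eigenfunction's largest-magnitude dual
coefficient positive.

### Multigroup extension

For G groups the between-group covariance Σ̂_B = Σᵢ (nᵢ/n)(μ̂ᵢ − μ̂)⊗²
is contracted against the truncated within-covariance inverse:
stat = n·tr(Σ̂_{W,T}⁻¹ Σ̂_B), referred to χ²(T·(G−1)).  At G = 2 this
reduces algebraically (and in tests, to 1e-10) to the two-sample
statistic.  The G−1 leading generalized eigenvectors of Σ̂_B against
Σ̂_{W,T} give the discriminant axes.  The degrees-of-freedom convention
is the standard multigroup discriminant-analysis asymptotic; it is
validated empirically by null calibration (three identical Gaussian
groups of 60 cells × 3 features, 400 replicates, rejection within
[0.025, 0.075] at α = 0.05) rather than taken from a closed-form
reference.

### Discriminant axis

h*_T ∝ Σ_t (⟨ê_t, μ̂₂ − μ̂₁⟩/λ̂_t)·ê_t, normalized to unit feature-space
norm; the Fisher ratio attains D̂²_T at h*_T (asserted to 1e-8).
Per-cell scores are ⟨φ(Y) − μ̂_pooled, h*_T⟩ — centered at zero across
all cells, a convention chosen here since only relative geometry is
meaningful — and oriented so the second group has the larger mean
score.  Extreme scores flag the cells carrying the discriminating
signal; this is the diagnostic surface for sub-population hunting
(mixture-model calling on scores is intentionally left to downstream
tooling and only the scores are exported).

## Kernels

* **Gauss** (default): exp(−‖y−y′‖²/2σ²).  Bandwidth σ² = median of
  squared Euclidean distances over all unordered pairs of distinct
  cells, pooled across groups, self-pairs excluded.  *Robustness rule:*
  on heavily zero-inflated count genes the plain median is often
  exactly 0 (zero–zero ties are the majority) although positive
  distances exist; `kfdiff` then falls back to the median of the
  strictly positive squared distances with a warning.  Only an
  all-identical sample is a hard error.  Zero distances between
  distinct duplicate cells are otherwise kept in the median.
* **Linear**: the scalar product; included to expose what
  non-linearity buys (and for the exact Hotelling correspondence).
* **ZI-Gauss** (univariate only): each observation is represented as
  π·δ₀ + (1−π)·N(μ, σ) with π the group's zero proportion and μ the
  observed value; the kernel is the L² product of two such densities,

      ππ′ + π(1−π′)f_{μ′,σ}(0) + (1−π)π′f_{μ,σ}(0) + (1−π)(1−π′)·k_comp(μ, μ′).

  Two conventions for the Gaussian component k_comp coexist: the
  normalized probability-product form (1/4πσ²)·exp(−(μ−μ′)²/4σ²)
  (default — it is the only form consistent with the density-product
  derivation that produces the f(0) cross terms) and an unnormalized
  exp(−(μ−μ′)²/2σ²) selectable via `zi_component="results"`.  σ is
  the median distance between non-zero observations.  π defaults to
  the per-group empirical zero fraction and can be supplied (e.g. the
  known dropout rate in simulations).

  *Known limitation:* with the ∫δ₀δ₀ = 1 convention implicit in the
  ππ′ term, this kernel is not positive semi-definite for all inputs
  (the δ₀/Gaussian cross-block can be indefinite when f_{μ,σ}(0)² >
  k_comp(μ,μ)).  The spectral truncation keeps only positive
  within-covariance directions, so the test remains well defined; the
  Gram itself should not be assumed PSD.

Bandwidths are always calibrated on the data as given (raw counts or
any normalization the caller applied), before any batch correction.

## Batch correction

φ̃(Y) = φ(Y) − μ̂_batch(Y) + μ̂_overall, computed purely in Gram
coordinates.  After correction all per-batch mean embeddings coincide
with the overall mean (between-batch MMD² = 0 to machine precision).
This additive mean-embedding correction is the minimal operator that
removes the batch location effect in feature space; it does not touch
higher-order batch differences (a genuinely open design point — see
Limitations).  Correction is applied after bandwidth calibration.

## Nystrom reduction

For large n, a stratified (proportional-per-group) uniform sample of m
landmark cells defines the feature map z(Y) = Λ^{−1/2}Uᵀk_L(Y); running
the linear-kernel pipeline on Z reproduces the Nystrom-approximated
Gram K_{·L}K_{LL}⁺K_{L·}.  With m = n the statistic is exact (asserted
to 1e-8); at m = n/3 on smooth Gaussian data the median relative
statistic error over seeds is under 15%.  Opt-in, seed mandatory.

## ZINB simulation benchmark

The generator emulates gene-wise counts under six shapes built from
negative-binomial mixtures with per-gene dropout ~ U[0.7, 0.9]:

| kind | condition 1 | condition 2 | note |
|---|---|---|---|
| DE | NB(10, 15) | NB(30, 15) | mean shift |
| DM | NB(10, 15) | ½NB(10) + ½NB(60) | one vs two modes |
| DP | 0.7/0.3 mix of NB(10), NB(60) | 0.3/0.7 mix | swapped proportions |
| DB | NB(35, 15) | ½NB(10) + ½NB(60) | equal means, different shape |
| H0_unimodal | NB(10, 15) | same | null |
| H0_bimodal | ½NB(10) + ½NB(60) | same | null |

(NB(μ, r): mean μ, size/dispersion r; components use r = 15 so the two
modes are clearly separated before dropout.)  These component values
are this package's own calibration choice, kept in a versioned catalog
(`DEFAULT_CATALOG`) so they can be replaced wholesale; the DB entry
enforces equal marginal means by construction.  The full-scale layout
is 10 000 genes per replicate — 250 genes for each alternative and
4500 for each null shape — with 100 cells per condition; tests and the
acceptance script scale the gene count down (e.g. 1000 null genes for
the type-I check) while keeping cell counts and dropout at the
full-scale values.  Per-gene seeds derive from SeedSequence([seed,
gene]) so results are gene-order independent.  No library-size effect
is added.

What passing the benchmark shows — and does not: calibration and power
are demonstrated under ZINB mixtures with group-homogeneous dropout
and independent genes.  Real single-cell data have correlated genes,
cell-level size factors and batch structure; the benchmark says
nothing about those axes.

## Error rates

Type-I error and power are computed on raw p-values (overall and per
alternative), FDR and TDR on Benjamini-Hochberg adjusted p-values,
with FDR = 0 when nothing is rejected.  α defaults to 0.05.

## Numerical and degenerate-input policy

* Constant (pooled) features in gene-wise runs are reported with
  p = 1 and flag `degenerate`, never an exception.
* Identical samples make the discriminant axis undefined (relative
  threshold 1e-9 on the mean-difference coordinates) — a hard error,
  since a direction would be meaningless.
* Permutation p-values can never be 0 by construction; B defaults to
  1000 and a seed is mandatory on every stochastic path (permutation,
  Nystrom, simulation), making reruns byte-identical.

## Problem sizes used in validation

Suite-internal simulations use: 1000 genes × 200 cells for the ZINB
type-I check; 300 replicates at n = 500 for the χ² null; 100
replicates at n = 400 with B = 500 for permutation/asymptotic
agreement; 300 DB genes at 50 cells per condition for the power
ordering; 400 replicates of 3 × 60 cells for multigroup calibration.
These sizes are the package's validation design; the estimators
themselves have no size limits beyond memory (O(n²) Gram storage).

## Known limitations

* The ZI-Gauss kernel is indefinite in corners of parameter space (see
  above) and defined univariately only.
* Batch correction removes only the location component of a batch
  effect.
* Two-factor designs and contrast testing are out of scope.
* The multigroup degrees-of-freedom convention T·(G−1) is validated
  empirically, not derived from an external reference.
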