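# kfdiff

Kernel-based testing for single-cell differential analysis.

`kfdiff` compares cell populations — two conditions, or several groups
— from scRNA-Seq or single-cell epigenomic matrices by testing whether
the *distributions* of expression differ, not just their means.  It is
aimed at analysts who need differential expression that stays powerful
on distribution-shaped differences (bimodality shifts, proportion
changes, equal-mean shape changes) where t-tests and (pseudo)bulk
methods are blind, plus diagnostics that show *which cells* carry the
difference.

## The statistic

Each cell's profile Y is embedded by the feature map φ of a kernel
k(Y, Y′) = ⟨φ(Y), φ(Y′)⟩ (Gaussian by default, with median-heuristic
bandwidth; zero-inflated Gaussian and linear kernels are also
provided).  With empirical mean embeddings μ̂₁, μ̂₂ and pooled
within-condition covariance operator Σ̂_W truncated to its top-T
eigendirections, the test statistic is the kernel Fisher discriminant
(truncated Mahalanobis) distance

    D̂²_T = (n₁n₂/n) ‖Σ̂_{W,T}^{−1/2} (μ̂₂ − μ̂₁)‖²  ~  χ²(T) under H₀,

a normalized maximum mean discrepancy: Hotelling's T² carried out in
feature space.  Asymptotic χ²(T) p-values are the default (reasonable
for n ≥ 100); a label-permutation p-value is available for small
samples.  A multigroup generalization (χ²(T·(G−1))), a Nystrom
landmark approximation for large n, per-gene univariate testing with
Benjamini-Hochberg correction, embedding-level batch correction, and
projections of cells on the discriminant axis h*_T (the direction
maximizing the truncated Fisher ratio) are all included.  See
`docs/methods.md` for the full model description.

## Worked example

Simulate a 200-gene benchmark (100 cells per condition; 40 DE genes
split over the DE/DM/DP/DB alternatives, 160 null genes; per-gene
dropout uniform on [0.7, 0.9]) and test every gene with the Gaussian
kernel at T = 4:

```python
from kfdiff import KernelSpec, univariate_all
from kfdiff.simulate import simulate_benchmark, error_rates

bench = simulate_benchmark(n_cells=100, n_genes=200, de_fraction=0.2, seed=42)
table = univariate_all(bench.data, KernelSpec(), T=4)
print(table.head(5).round(4).to_string(index=False))
```

```
feature_id  statistic  df  pvalue  pvalue_adj  n1  n2  pi1  pi2  mean1  mean2 flag
        g0    14.9459   4  0.0048      0.0438 100 100 0.85 0.89   1.74   3.00   ok
        g1    20.0393   4  0.0005      0.0070 100 100 0.93 0.87   0.76   3.65   ok
        g2    26.1367   4  0.0000      0.0008 100 100 0.85 0.91   1.52   2.75   ok
        g3    44.6424   4  0.0000      0.0000 100 100 0.71 0.76   2.77   6.59   ok
        g4    21.1473   4  0.0003      0.0054 100 100 0.88 0.88   1.39   3.58   ok
```

Each row is one gene: the D̂²₄ statistic, its χ²(4) p-value, the
BH-adjusted p-value, per-condition zero proportions (`pi1`, `pi2`) and
means.  Scoring against the simulation truth:

```python
rates = error_rates(table["pvalue"], table["pvalue_adj"], bench.truth, alpha=0.05)
print(rates.round(3).to_string())
```

```
type_I_error     0.019
power            0.750
power_DE         1.000
power_DM         0.700
power_DP         0.500
power_DB         0.800
FDR              0.000
TDR              1.000
n_rejections    22.000
alpha            0.050
```

Type-I error on the null genes sits at the nominal level, power is
high even on the equal-means DB alternative (where a t-test has none),
and no false discoveries survive BH correction.

The same pipeline is available from the shell:

```sh
kfdiff simulate --n-cells 100 --n-genes 200 --de-fraction 0.2 --seed 42 \
    --benchmark --out sim/
kfdiff test --counts sim/counts.tsv --meta sim/meta.tsv --mode univariate --out run/
kfdiff project --counts sim/counts.tsv --meta sim/meta.tsv --t 4 --out proj/
```

`test` writes `results.tsv` (and per-cell `projections.tsv` in
multivariate mode), `project` writes discriminant-axis and kernel-PCA
coordinates per cell, and every command writes a `manifest.json` that
reproduces its outputs byte-for-byte given the same seed.

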