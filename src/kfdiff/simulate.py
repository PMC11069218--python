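"""Zero-inflated negative-binomial simulation benchmark.

Genes are drawn from mixtures of zero-inflated negative binomials
reproducing the four canonical distributional alternatives (DE: mean
shift; DM: one vs two modes; DP: same two modes with swapped
proportions; DB: two modes vs one intermediate mode with **equal
marginal means**) plus two null shapes (unimodal and bimodal, identical
across conditions).  Per-gene dropout probabilities are drawn uniformly
on [0.7, 0.9], emulating the sparsity of non-UMI scRNA-Seq.

The component means, dispersions and mixture weights live in
:data:`DEFAULT_CATALOG` (a versioned parameter catalog) so they can be
swapped wholesale; the DB entry solves w·μ_low + (1−w)·μ_high = μ_uni
by construction.  Randomness flows through a single seeded generator
with per-gene substreams, so gene-level draws are reproducible
independently of gene order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import Dataset

__all__ = [
    "AlternativeSpec",
    "DEFAULT_CATALOG",
    "ALTERNATIVES",
    "NULL_KINDS",
    "simulate_gene",
    "simulate_benchmark",
    "error_rates",
]

ALTERNATIVES = ("DE", "DM", "DP", "DB")
NULL_KINDS = ("H0_unimodal", "H0_bimodal")


@dataclass(frozen=True)
class AlternativeSpec:
    """Mixture-of-ZINB description of one gene under both conditions.

    ``components[i]`` is the list of (NB mean, NB size) pairs for
    condition i (i = 0, 1) and ``weights[i]`` the matching mixture
    weights; ``dropout`` is the probability of replacing a draw by an
    excess zero (shared by both conditions).
    """

    kind: str
    components: tuple = ()
    weights: tuple = ()
    dropout: float = 0.8

    def __post_init__(self) -> None:
        if len(self.components) != 2 or len(self.weights) != 2:
            raise ValueError("components/weights must give both conditions")
        for i in range(2):
            w = np.asarray(self.weights[i], dtype=float)
            if np.any(w < 0) or np.any(w > 1) or not np.isclose(w.sum(), 1.0):
                raise ValueError(f"mixture weights of condition {i + 1} must lie in [0,1] and sum to 1")
            if len(w) != len(self.components[i]):
                raise ValueError("weights and components disagree in length")
            for mean, size in self.components[i]:
                if mean <= 0 or size <= 0:
                    raise ValueError(f"invalid NB parameters (mean={mean}, size={size})")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must lie in [0, 1]")

    def marginal_means(self) -> tuple[float, float]:
        """Pre-dropout mixture means per condition."""
        out = []
        for i in range(2):
            w = np.asarray(self.weights[i], dtype=float)
            mu = np.array([m for m, _ in self.components[i]])
            out.append(float(w @ mu))
        return tuple(out)


_LOW, _HIGH, _SIZE = 10.0, 60.0, 15.0
_DB_W = 0.5
_DB_UNI = _DB_W * _LOW + (1.0 - _DB_W) * _HIGH  # equal-means constraint

#: versioned default parameter catalog (v1)
DEFAULT_CATALOG: dict[str, AlternativeSpec] = {
    "DE": AlternativeSpec(
        "DE",
        components=(((_LOW, _SIZE),), ((3.0 * _LOW, _SIZE),)),
        weights=((1.0,), (1.0,)),
    ),
    "DM": AlternativeSpec(
        "DM",
        components=(((_LOW, _SIZE),), ((_LOW, _SIZE), (_HIGH, _SIZE))),
        weights=((1.0,), (0.5, 0.5)),
    ),
    "DP": AlternativeSpec(
        "DP",
        components=(((_LOW, _SIZE), (_HIGH, _SIZE)), ((_LOW, _SIZE), (_HIGH, _SIZE))),
        weights=((0.7, 0.3), (0.3, 0.7)),
    ),
    "DB": AlternativeSpec(
        "DB",
        components=(((_DB_UNI, _SIZE),), ((_LOW, _SIZE), (_HIGH, _SIZE))),
        weights=((1.0,), (_DB_W, 1.0 - _DB_W)),
    ),
    "H0_unimodal": AlternativeSpec(
        "H0_unimodal",
        components=(((_LOW, _SIZE),), ((_LOW, _SIZE),)),
        weights=((1.0,), (1.0,)),
    ),
    "H0_bimodal": AlternativeSpec(
        "H0_bimodal",
        components=(((_LOW, _SIZE), (_HIGH, _SIZE)), ((_LOW, _SIZE), (_HIGH, _SIZE))),
        weights=((0.5, 0.5), (0.5, 0.5)),
    ),
}


def _with_dropout(spec: AlternativeSpec, dropout: float) -> AlternativeSpec:
    return AlternativeSpec(spec.kind, spec.components, spec.weights, dropout)


def _draw_condition(
    rng: np.random.Generator, components, weights, dropout: float, n: int
) -> np.ndarray:
    comp = rng.choice(len(weights), size=n, p=np.asarray(weights, dtype=float))
    out = np.empty(n)
    for c, (mean, size) in enumerate(components):
        mask = comp == c
        # NB(size r, mean μ): p = r / (r + μ)
        out[mask] = rng.negative_binomial(size, size / (size + mean), size=mask.sum())
    out[rng.random(n) < dropout] = 0.0
    return out


def simulate_gene(
    spec: AlternativeSpec, n1: int, n2: int, seed: int | np.random.SeedSequence
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one gene: n1 counts under condition 1, n2 under condition 2."""
    if n1 < 1 or n2 < 1:
        raise ValueError("both conditions need at least one cell")
    rng = np.random.default_rng(seed)
    y1 = _draw_condition(rng, spec.components[0], spec.weights[0], spec.dropout, n1)
    y2 = _draw_condition(rng, spec.components[1], spec.weights[1], spec.dropout, n2)
    return y1, y2


@dataclass
class BenchmarkData:
    """Simulated dataset plus the gene-level ground truth."""

    data: Dataset
    truth: pd.DataFrame
    dropout: np.ndarray = field(repr=False, default=None)


def benchmark_layout(n_genes: int, de_fraction: float = 0.1) -> list[str]:
    """Gene kinds: DE genes split equally over the four alternatives,
    null genes split equally between the unimodal and bimodal shapes."""
    n_de = int(round(n_genes * de_fraction))
    per_alt, rem = divmod(n_de, 4)
    kinds = []
    for i, kind in enumerate(ALTERNATIVES):
        kinds.extend([kind] * (per_alt + (1 if i < rem else 0)))
    n_h0 = n_genes - n_de
    per_h0, rem0 = divmod(n_h0, 2)
    kinds.extend(["H0_unimodal"] * (per_h0 + rem0))
    kinds.extend(["H0_bimodal"] * per_h0)
    return kinds


def simulate_benchmark(
    n_cells: int = 100,
    n_genes: int = 10000,
    de_fraction: float = 0.1,
    dropout_range: tuple[float, float] = (0.7, 0.9),
    seed: int = 0,
    catalog: dict[str, AlternativeSpec] | None = None,
) -> BenchmarkData:
    """Full benchmark matrix: ``n_cells`` per condition × ``n_genes``.

    The default layout reproduces the reference design at full scale —
    10% DE genes split 250/250/250/250 over DE/DM/DP/DB and the
    remaining 9000 split 4500/4500 over the two null shapes — and
    scales proportionally for smaller ``n_genes``.  Per-gene dropout is
    drawn uniformly on ``dropout_range``.
    """
    catalog = catalog or DEFAULT_CATALOG
    kinds = benchmark_layout(n_genes, de_fraction)
    root = np.random.SeedSequence(seed)
    lo, hi = dropout_range
    dropout = np.random.default_rng(root.spawn(1)[0]).uniform(lo, hi, size=n_genes)
    values = np.empty((2 * n_cells, n_genes))
    for g, kind in enumerate(kinds):
        spec = _with_dropout(catalog[kind], float(dropout[g]))
        y1, y2 = simulate_gene(spec, n_cells, n_cells, np.random.SeedSequence([seed, g]))
        values[:n_cells, g] = y1
        values[n_cells:, g] = y2
    condition = pd.Series(["cond1"] * n_cells + ["cond2"] * n_cells)
    feature_names = [f"g{g}" for g in range(n_genes)]
    data = Dataset(values, condition, feature_names=feature_names)
    truth = pd.DataFrame(
        {
            "feature_id": feature_names,
            "kind": kinds,
            "is_de": [k in ALTERNATIVES for k in kinds],
            "dropout": dropout,
        }
    )
    return BenchmarkData(data=data, truth=truth, dropout=dropout)


def error_rates(
    pvalues,
    adjusted,
    truth: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.Series:
    """Benchmark metrics from aligned p-value vectors and the truth table.

    Type-I error and power use raw p-values (overall and per
    alternative); FDR and TDR use the BH-adjusted ones, with the
    no-rejection convention FDR = 0.
    """
    p = np.asarray(pvalues, dtype=float)
    padj = np.asarray(adjusted, dtype=float)
    if not (len(p) == len(padj) == len(truth)):
        raise ValueError("p-value vectors and truth table must be aligned")
    is_de = truth["is_de"].to_numpy(dtype=bool)
    kind = truth["kind"].to_numpy()
    out = {}
    h0 = ~is_de
    out["type_I_error"] = float(np.mean(p[h0] < alpha)) if h0.any() else np.nan
    out["power"] = float(np.mean(p[is_de] < alpha)) if is_de.any() else np.nan
    for alt in ALTERNATIVES:
        mask = kind == alt
        out[f"power_{alt}"] = float(np.mean(p[mask] < alpha)) if mask.any() else np.nan
    rejected = padj < alpha
    n_rej = int(rejected.sum())
    fp = int((rejected & h0).sum())
    tp = int((rejected & is_de).sum())
    out["FDR"] = fp / max(1, n_rej)
    out["TDR"] = tp / max(1, n_rej)
    out["n_rejections"] = n_rej
    out["alpha"] = alpha
    return pd.Series(out)
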