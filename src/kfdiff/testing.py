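"""Kernel two-sample and multigroup tests on mean embeddings.

The headline statistic is the truncated kernel Fisher discriminant
(Mahalanobis) statistic

    D̂²_T = (n₁n₂/n) · ‖Σ̂_{W,T}^{−1/2} (μ̂₂ − μ̂₁)‖²
         = (n₁n₂/n) · Σ_{t≤T} ⟨ê_t, μ̂₂ − μ̂₁⟩² / λ̂_t ,

which standardizes the mean-embedding difference by the top-T spectrum
of the pooled within-condition covariance operator and follows χ²(T)
asymptotically under H₀ (the Hotelling test carried out in the feature
space).  The unstandardized MMD² and a label-permutation procedure are
provided alongside, plus the multigroup generalization, a Nystrom
landmark reduction for large n, and the gene-wise univariate loop with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .dataset import Dataset
from .embedding import (
    DiffCoordinates,
    GramDecomposition,
    _as_categorical,
    _center_vector_within,
    _group_index,
    _top_spectrum,
    center_gram_within,
    diff_coordinates,
    mean_difference_vector,
    within_spectrum,
)
from .kernels import (
    DegenerateBandwidthError,
    GramMatrix,
    KernelSpec,
    compute_gram,
    cross_gram,
    estimate_zero_proportions,
)

__all__ = [
    "TestResult",
    "MultigroupResult",
    "mmd2",
    "kfda_statistic",
    "asymptotic_pvalue",
    "two_sample_test",
    "permutation_test",
    "multigroup_test",
    "nystrom_reduce",
    "univariate_all",
    "bh_adjust",
]

#: default truncations: T=4 gene-wise, T=10 whole-transcriptome
DEFAULT_T_UNIVARIATE = 4
DEFAULT_T_MULTIVARIATE = 10

#: below this pooled sample size the asymptotic χ² approximation is shaky
ASYMPTOTIC_MIN_N = 100


@dataclass
class TestResult:
    """Two-sample kernel test output across truncations 1..T."""

    statistic_by_t: dict
    mmd2: float
    pvalue_asymptotic: dict
    n1: int
    n2: int
    kernel: KernelSpec
    truncation: int
    pvalue_permutation: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    null_statistics: np.ndarray | None = field(default=None, repr=False)

    @property
    def statistic(self) -> float:
        return self.statistic_by_t[self.truncation]

    @property
    def pvalue(self) -> float:
        if self.pvalue_permutation is not None:
            return self.pvalue_permutation
        return self.pvalue_asymptotic[self.truncation]


def mmd2(gram: GramMatrix, labels) -> float:
    """Plug-in (V-statistic) MMD²: ‖μ̂₁ − μ̂₂‖² from pairwise similarities.

    mean(K₁₁) + mean(K₂₂) − 2·mean(K₁₂), diagonals included, which is
    exactly the squared RKHS distance between empirical mean embeddings.
    """
    labels = _as_categorical(labels)
    codes, levels, _ = _group_index(labels)
    if len(levels) != 2:
        raise ValueError("mmd2 is a two-sample statistic")
    K = gram.values
    m1, m2 = codes == 0, codes == 1
    return float(
        K[np.ix_(m1, m1)].mean() + K[np.ix_(m2, m2)].mean() - 2.0 * K[np.ix_(m1, m2)].mean()
    )


def kfda_statistic(decomp: GramDecomposition, diff: DiffCoordinates) -> dict:
    """Truncated Mahalanobis statistic for every truncation t = 1..T.

    D̂²_t = (n₁n₂/n)·Σ_{s≤t} coords[s]²/λ_s — non-decreasing in t.
    """
    lam = decomp.eigenvalues
    if np.any(lam <= 0):
        raise RuntimeError("decomposition contract violated: non-positive retained eigenvalue")
    if len(diff.coords) != len(lam):
        raise ValueError("decomposition and coordinates disagree on T")
    n1, n2 = diff.n1, diff.n2
    scale = n1 * n2 / (n1 + n2)
    increments = diff.coords**2 / lam
    cum = scale * np.cumsum(increments)
    return {t + 1: float(cum[t]) for t in range(len(cum))}


def asymptotic_pvalue(statistic: float, t: int) -> float:
    """Upper tail of χ²(t), the asymptotic null distribution of D̂²_t."""
    if t < 1:
        raise ValueError("degrees of freedom t must be ≥ 1")
    if statistic < 0:
        raise ValueError("statistic must be nonnegative")
    return float(scipy.stats.chi2.sf(statistic, df=t))


def _resolve_spec(data: Dataset, spec: KernelSpec) -> KernelSpec:
    spec = spec.resolve_bandwidth(data)
    return spec


def two_sample_test(
    data: Dataset,
    spec: KernelSpec | None = None,
    T: int = DEFAULT_T_MULTIVARIATE,
    gram: GramMatrix | None = None,
    warn_small_n: bool = True,
) -> TestResult:
    """Full two-sample pipeline: Gram → spectrum → D̂²_t → χ² p-values.

    An already-built (possibly batch-corrected) Gram can be passed to
    skip kernel evaluation.
    """
    data.require_groups(min_levels=2)
    if len(data.condition_levels) != 2:
        raise ValueError("two_sample_test needs exactly 2 conditions; see multigroup_test")
    if gram is None:
        gram = compute_gram(data, spec or KernelSpec())
    if warn_small_n and data.n_cells < ASYMPTOTIC_MIN_N:
        warnings.warn(
            f"n={data.n_cells} < {ASYMPTOTIC_MIN_N}: the χ²(T) approximation may be "
            "inaccurate; consider permutation_test",
            RuntimeWarning,
            stacklevel=2,
        )
    decomp = within_spectrum(gram, data.condition, T)
    if decomp.T == 0:
        raise DegenerateBandwidthError("zero within-group variability: test undefined")
    diff = diff_coordinates(gram, data.condition, decomp)
    stats = kfda_statistic(decomp, diff)
    pvals = {t: asymptotic_pvalue(s, t) for t, s in stats.items()}
    return TestResult(
        statistic_by_t=stats,
        mmd2=mmd2(gram, data.condition),
        pvalue_asymptotic=pvals,
        n1=diff.n1,
        n2=diff.n2,
        kernel=gram.kernel,
        truncation=decomp.T,
    )


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def _stat_from_gram(K: np.ndarray, codes: np.ndarray, T: int) -> float:
    """D̂²_T recomputed for one label assignment on a fixed Gram.

    Only label-dependent quantities (centering, spectrum, difference
    coordinates) are recomputed; the Gram itself is fixed.
    """
    n = K.shape[0]
    counts = np.bincount(codes, minlength=2)
    C = np.stack([K[:, codes == g].mean(axis=1) for g in range(2)], axis=1)
    E = np.stack([C[codes == g].mean(axis=0) for g in range(2)], axis=0)
    Kc = K - C[:, codes] - C[:, codes].T + E[np.ix_(codes, codes)]
    Kc = (Kc + Kc.T) / 2.0
    # the permutation loop only ever needs the top-T pairs: Lanczos
    # beats the dense solver well below the general-purpose threshold
    w, U = _top_spectrum(Kc, min(n - 2, T), dense_limit=150)
    lam = w / n
    keep = lam > 1e-12 * max(lam[0], np.finfo(float).tiny)
    lam, U = lam[keep], U[:, keep]
    if lam.size == 0:
        return 0.0
    d = mean_difference_vector(codes, counts)
    Pv = _center_vector_within(K @ d, codes, 2)
    coords = (U.T @ Pv) / np.sqrt(n * lam)
    return float(counts[0] * counts[1] / n * np.sum(coords**2 / lam))


def permutation_test(
    data: Dataset,
    spec: KernelSpec | None = None,
    T: int = DEFAULT_T_MULTIVARIATE,
    B: int = 1000,
    seed: int | None = None,
    gram: GramMatrix | None = None,
) -> TestResult:
    """Label-permutation null for D̂²_T on a fixed Gram.

    p = (1 + #{b : D̂²_T(b) ≥ D̂²_T(obs)}) / (B + 1), never exactly 0.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    if seed is None:
        raise ValueError("permutation_test requires a seed for reproducibility")
    data.require_groups(min_levels=2)
    if len(data.condition_levels) != 2:
        raise ValueError("permutation_test is two-sample")
    n = data.n_cells
    codes = data.condition.cat.codes.to_numpy()
    if n < 4 or len(set(codes)) < 2:
        raise ValueError("sample too small for distinct permutations")
    if gram is None:
        gram = compute_gram(data, spec or KernelSpec())
    K = gram.values
    T_eff = min(T, n - 2)
    observed = _stat_from_gram(K, codes, T_eff)
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        null[b] = _stat_from_gram(K, rng.permutation(codes), T_eff)
    p_perm = (1.0 + np.sum(null >= observed)) / (B + 1.0)
    counts = np.bincount(codes, minlength=2)
    return TestResult(
        statistic_by_t={T_eff: observed},
        mmd2=mmd2(gram, data.condition),
        pvalue_asymptotic={T_eff: asymptotic_pvalue(observed, T_eff)},
        n1=int(counts[0]),
        n2=int(counts[1]),
        kernel=gram.kernel,
        truncation=T_eff,
        pvalue_permutation=float(p_perm),
        n_permutations=B,
        seed=seed,
        null_statistics=null,
    )


# ---------------------------------------------------------------------------
# multigroup generalization
# ---------------------------------------------------------------------------

@dataclass
class MultigroupResult:
    """Multigroup kernel FDA test: trace statistic and discriminant axes."""

    statistic: float
    pvalue: float
    df: int
    truncation: int
    n_groups: int
    group_sizes: dict
    eigenvalues: np.ndarray
    #: T × (G−1) coefficients of the discriminant axes in the ê_t basis
    axis_coefficients: np.ndarray
    #: variance separated along each discriminant axis (descending)
    axis_spectrum: np.ndarray


def multigroup_test(
    data: Dataset,
    spec: KernelSpec | None = None,
    T: int = DEFAULT_T_MULTIVARIATE,
    gram: GramMatrix | None = None,
) -> MultigroupResult:
    """G-group kernel discriminant test.

    The between-group covariance Σ̂_B = Σ_i (n_i/n)(μ̂_i − μ̂)⊗² is
    contracted against the truncated within-covariance inverse:

        stat = n · tr(Σ̂_{W,T}⁻¹ Σ̂_B) = Σ_t Σ_i n_i ⟨ê_t, μ̂_i − μ̂⟩² / λ_t,

    compared to χ²(T·(G−1)).  With G = 2 this reduces exactly to the
    two-sample D̂²_T.  The G−1 leading generalized eigenvectors give the
    discriminant axes (expressed in the within-PCA basis).
    """
    data.require_groups(min_levels=2)
    if gram is None:
        gram = compute_gram(data, spec or KernelSpec())
    labels = _as_categorical(data.condition)
    codes, levels, counts = _group_index(labels)
    G = len(levels)
    n = gram.n
    decomp = within_spectrum(gram, labels, T)
    if decomp.T == 0:
        raise DegenerateBandwidthError("zero within-group variability: test undefined")
    lam = decomp.eigenvalues
    A = decomp.dual_coefficients
    K = gram.values
    # c[t, i] = ⟨ê_t, μ̂_i − μ̂⟩ via d_i = (1/n_i)·1_i − (1/n)·1
    C = np.empty((decomp.T, G))
    for g in range(G):
        d = np.full(n, -1.0 / n)
        d[codes == g] += 1.0 / counts[g]
        C[:, g] = A.T @ _center_vector_within(K @ d, codes, G)
    stat = float(np.sum(counts[None, :] * C**2 / lam[:, None]))
    df = decomp.T * (G - 1)
    p = asymptotic_pvalue(stat, df)
    # discriminant axes: generalized eigenproblem of Σ_B against Σ_{W,T},
    # solved in the ê_t basis where Σ_{W,T} is diag(λ)
    M = (C * (counts / n)[None, :]) @ C.T
    S = (M / np.sqrt(lam)[:, None]) / np.sqrt(lam)[None, :]
    w, V = np.linalg.eigh((S + S.T) / 2.0)
    order = np.argsort(w)[::-1][: G - 1]
    axes = V[:, order] / np.sqrt(lam)[:, None]
    norms = np.linalg.norm(V[:, order], axis=0)
    axes = axes / np.where(norms > 0, norms, 1.0)
    return MultigroupResult(
        statistic=stat,
        pvalue=p,
        df=df,
        truncation=decomp.T,
        n_groups=G,
        group_sizes={levels[g]: int(counts[g]) for g in range(G)},
        eigenvalues=lam,
        axis_coefficients=axes,
        axis_spectrum=w[order],
    )


# ---------------------------------------------------------------------------
# Nystrom reduction
# ---------------------------------------------------------------------------

def nystrom_reduce(
    data: Dataset,
    spec: KernelSpec | None = None,
    n_landmarks: int = 200,
    seed: int | None = None,
    T: int | None = None,
) -> Dataset:
    """Landmark (Nystrom) feature map for large samples.

    Samples landmarks stratified by condition (proportional allocation),
    then maps every cell to its coordinates in the landmark-spanned
    subspace, Z = K_{·L} U Λ^{−1/2}.  The returned Dataset, used with
    the **linear** kernel, induces the Nystrom-approximated Gram
    Z Zᵀ = K_{·L} K_{LL}⁺ K_{L·}; with n_landmarks = n the
    approximation is exact.
    """
    if seed is None:
        raise ValueError("nystrom_reduce requires a seed")
    n = data.n_cells
    if n_landmarks > n:
        raise ValueError(f"n_landmarks={n_landmarks} exceeds n={n}")
    G = len(data.condition_levels)
    if T is not None and n_landmarks < T + G:
        raise ValueError(f"n_landmarks must be ≥ T + #conditions = {T + G}")
    spec = (spec or KernelSpec()).resolve_bandwidth(data)
    if spec.family == "zi_gauss" and (spec.zero_inflation is None or spec.zi_sigma is None):
        from .kernels import zi_sigma_from_nonzero

        spec = KernelSpec(
            family="zi_gauss",
            bandwidth=spec.bandwidth,
            zero_inflation=estimate_zero_proportions(data).to_dict(),
            zi_sigma=zi_sigma_from_nonzero(data),
            zi_component=spec.zi_component,
        )
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    indices = data.group_indices()
    sizes = data.group_sizes()
    total = 0
    for level in data.condition_levels:
        share = int(round(n_landmarks * sizes[level] / n))
        share = max(1, min(share, sizes[level]))
        chosen.append(rng.choice(indices[level], size=share, replace=False))
        total += share
    # proportional rounding can over/undershoot by a cell or two
    landmarks = np.sort(np.concatenate(chosen))
    if total > n_landmarks:
        landmarks = np.sort(rng.choice(landmarks, size=n_landmarks, replace=False))
    lm_data = data.subset(landmarks)
    K_ll = cross_gram(lm_data, lm_data, spec)
    K_xl = cross_gram(data, lm_data, spec)
    w, U = np.linalg.eigh((K_ll + K_ll.T) / 2.0)
    keep = w > 1e-12 * max(w.max(), np.finfo(float).tiny)
    Z = K_xl @ U[:, keep] / np.sqrt(w[keep])[None, :]
    return Dataset(
        Z,
        data.condition,
        batch=data.batch,
        feature_names=[f"nystrom{j}" for j in range(Z.shape[1])],
        cell_ids=data.cell_ids,
    )


# ---------------------------------------------------------------------------
# gene-wise loop
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-value passed to BH adjustment")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def univariate_all(
    data: Dataset,
    spec: KernelSpec | None = None,
    T: int = DEFAULT_T_UNIVARIATE,
    mode: str = "asymptotic",
    B: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gene-wise two-sample kernel tests with BH correction.

    Each feature is tested independently: the bandwidth is recalibrated
    per feature (median heuristic), and the zero-inflated kernel uses
    per-feature zero proportions.  Features that are constant in the
    pooled sample (degenerate bandwidth) are reported with p = 1 and a
    ``degenerate`` flag rather than aborting the run.
    """
    if mode not in ("asymptotic", "permutation"):
        raise ValueError("mode must be 'asymptotic' or 'permutation'")
    data.require_groups(min_levels=2)
    if len(data.condition_levels) != 2:
        raise ValueError("univariate_all is two-sample")
    spec = spec or KernelSpec()
    lv1, lv2 = data.condition_levels
    idx = data.group_indices()
    rows = []
    for g, name in enumerate(data.feature_names):
        col = data.values[:, g]
        sub = Dataset(
            col[:, None], data.condition, feature_names=[name], cell_ids=data.cell_ids
        )
        pi1 = float(np.mean(col[idx[lv1]] == 0))
        pi2 = float(np.mean(col[idx[lv2]] == 0))
        mean1 = float(col[idx[lv1]].mean())
        mean2 = float(col[idx[lv2]].mean())
        base = dict(
            feature_id=name, n1=len(idx[lv1]), n2=len(idx[lv2]),
            pi1=pi1, pi2=pi2, mean1=mean1, mean2=mean2,
        )
        try:
            if mode == "asymptotic":
                res = two_sample_test(sub, spec, T=T, warn_small_n=False)
                stat, df, p = res.statistic, res.truncation, res.pvalue_asymptotic[res.truncation]
            else:
                res = permutation_test(sub, spec, T=T, B=B, seed=_feature_seed(seed, g))
                stat, df, p = res.statistic_by_t[res.truncation], res.truncation, res.pvalue
            rows.append({**base, "statistic": stat, "df": df, "pvalue": p, "flag": "ok"})
        except DegenerateBandwidthError:
            rows.append(
                {**base, "statistic": 0.0, "df": 0, "pvalue": 1.0, "flag": "degenerate"}
            )
    table = pd.DataFrame(rows)
    table["pvalue_adj"] = bh_adjust(table["pvalue"].to_numpy())
    cols = [
        "feature_id", "statistic", "df", "pvalue", "pvalue_adj",
        "n1", "n2", "pi1", "pi2", "mean1", "mean2", "flag",
    ]
    return table[cols]


def _feature_seed(seed: int | None, g: int) -> int:
    if seed is None:
        raise ValueError("permutation mode requires a seed")
    return int(np.random.SeedSequence([seed, g]).generate_state(1)[0] % (2**31 - 1))
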