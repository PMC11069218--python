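"""Feature-space linear algebra carried out in Gram coordinates.

All estimators live in the RKHS but are computed through the n × n Gram
matrix.  With Φ the (implicit) matrix of embedded cells and P the
block-diagonal per-condition centering projector, the pooled
within-group covariance operator Σ̂_W = (1/n) Φ P Φᵀ shares its nonzero
spectrum with (1/n) P K P, so its top-T eigenpairs — the kernel-PCA
directions of condition-centered expression — are obtained from the
centered Gram.  Eigenfunctions are stored through their dual
coefficients: ê_t = Φ P a_t with a_t = u_t / √(n λ_t), which makes them
unit-norm in the feature space.

Covariances use the biased 1/n_i normalization throughout, matching the
plug-in mean-embedding estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse.linalg

from .kernels import GramMatrix

__all__ = [
    "GramDecomposition",
    "DiffCoordinates",
    "center_gram_within",
    "within_spectrum",
    "diff_coordinates",
    "batch_correct_gram",
]

#: eigenvalues below RANK_RTOL · λ₁ are treated as numerically zero
RANK_RTOL = 1e-12

#: above this size the truncated spectrum is computed with a Lanczos
#: solver instead of a full dense eigendecomposition
_DENSE_LIMIT = 450


def _as_categorical(labels) -> pd.Series:
    s = labels if isinstance(labels, pd.Series) else pd.Series(np.asarray(labels))
    return s.astype("category")


def _group_index(labels: pd.Series) -> tuple[np.ndarray, list, np.ndarray]:
    """codes, level list and level counts of a categorical label vector."""
    codes = labels.cat.codes.to_numpy()
    levels = list(labels.cat.categories)
    counts = np.bincount(codes, minlength=len(levels))
    return codes, levels, counts


def center_gram_within(gram: GramMatrix | np.ndarray, labels) -> np.ndarray:
    """Per-condition double centering P K P of the Gram matrix.

    P is block-diagonal with blocks I_{n_i} − (1/n_i)·J, so P K P is the
    Gram matrix of the embeddings centered by their own condition mean,
    φ(Y_{i,j}) − μ̂_i.  Within each condition block, row and column sums
    vanish.
    """
    K = gram.values if isinstance(gram, GramMatrix) else np.asarray(gram, dtype=float)
    labels = _as_categorical(labels)
    if len(labels) != K.shape[0]:
        raise ValueError(f"labels have length {len(labels)}, Gram is {K.shape[0]} × {K.shape[0]}")
    codes, levels, counts = _group_index(labels)
    if counts.min() < 2:
        small = [levels[g] for g in np.flatnonzero(counts < 2)]
        raise ValueError(f"every condition needs ≥2 cells for within-centering; too small: {small}")
    # column-group means C (n × G), then P K P = K − C[·,g_b] − C[·,g_a]ᵀ + E[g_a,g_b]
    C = np.stack([K[:, codes == g].mean(axis=1) for g in range(len(levels))], axis=1)
    E = np.stack([C[codes == g].mean(axis=0) for g in range(len(levels))], axis=0)
    Kc = K - C[:, codes] - C[:, codes].T + E[np.ix_(codes, codes)]
    return (Kc + Kc.T) / 2.0


def _center_vector_within(v: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    out = v.copy()
    for g in range(n_groups):
        mask = codes == g
        out[mask] -= v[mask].mean()
    return out


@dataclass
class GramDecomposition:
    """Truncated spectrum of the within-condition covariance operator.

    ``eigenvalues`` are the top-T eigenvalues λ_t of (1/n)·P K P (equal
    to the nonzero spectrum of Σ̂_W); ``dual_coefficients`` is the n × T
    matrix A whose column a_t expresses the unit-norm eigenfunction as
    ê_t = Σ_j A[j,t]·(φ(Y_j) − μ̂_{cond(j)}).
    """

    eigenvalues: np.ndarray
    dual_coefficients: np.ndarray
    labels: pd.Series
    n_effective_rank: int

    @property
    def T(self) -> int:
        return len(self.eigenvalues)

    @property
    def n(self) -> int:
        return self.dual_coefficients.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Columnar serialization (for caching): one column per axis."""
        cols = {f"pc{t + 1}": self.dual_coefficients[:, t] for t in range(self.T)}
        df = pd.DataFrame(cols)
        df.attrs["eigenvalues"] = list(self.eigenvalues)
        return df


def _top_spectrum(
    Kc: np.ndarray, k: int, dense_limit: int = _DENSE_LIMIT
) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenpairs of the symmetric PSD matrix Kc, descending."""
    n = Kc.shape[0]
    k = min(k, n)
    if n <= dense_limit or k > n // 4:
        w, U = np.linalg.eigh(Kc)
        order = np.argsort(w)[::-1][:k]
        return w[order], U[:, order]
    v0 = np.full(n, 1.0 / np.sqrt(n))
    w, U = scipy.sparse.linalg.eigsh(Kc, k=k, which="LA", v0=v0)
    order = np.argsort(w)[::-1]
    return w[order], U[:, order]


def within_spectrum(gram: GramMatrix, labels, T: int) -> GramDecomposition:
    """Top-T kernel-PCA decomposition of the within-group covariance.

    T is capped (with a warning) at the effective numerical rank of the
    condition-centered Gram; eigenvalues below ``RANK_RTOL``·λ₁ are
    never retained.  Ridge regularization is deliberately not offered —
    spectral truncation is the regularizer.
    """
    if T < 1:
        raise ValueError("T must be a positive integer")
    labels = _as_categorical(labels)
    n = gram.n
    G = len(labels.cat.categories)
    max_rank = n - G
    if T > max_rank:
        warnings.warn(
            f"T={T} exceeds the maximal rank n−G={max_rank}; capping", RuntimeWarning, stacklevel=2
        )
        T = max_rank
    Kc = center_gram_within(gram, labels)
    # a couple of spare eigenvalues so near-threshold rank is visible
    w, U = _top_spectrum(Kc, min(n, T + 2))
    lam = w / n
    if lam.size == 0 or lam[0] <= 0:
        warnings.warn("within-covariance is numerically zero: empty spectrum", RuntimeWarning,
                      stacklevel=2)
        return GramDecomposition(np.empty(0), np.empty((n, 0)), labels, 0)
    tol = RANK_RTOL * lam[0]
    keep = lam > tol
    n_rank = int(keep.sum())  # rank among the computed eigenvalues
    if keep[:T].sum() < T:
        warnings.warn(
            f"requested T={T} exceeds the effective rank {int(keep[:T].sum())}; capping",
            RuntimeWarning,
            stacklevel=2,
        )
    sel = np.flatnonzero(keep[:T] if keep.size >= T else keep)[:T]
    lam_T = lam[sel]
    A = U[:, sel] / np.sqrt(n * lam_T)[None, :]
    # deterministic orientation: largest-|coefficient| entry positive
    for t in range(A.shape[1]):
        j = np.argmax(np.abs(A[:, t]))
        if A[j, t] < 0:
            A[:, t] = -A[:, t]
    return GramDecomposition(lam_T, A, labels, max(n_rank, len(sel)))


@dataclass
class DiffCoordinates:
    """⟨ê_t, μ̂₂ − μ̂₁⟩ for t = 1..T, plus the group sizes."""

    coords: np.ndarray
    n1: int
    n2: int


def mean_difference_vector(codes: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Weight vector d with Φ d = μ̂₂ − μ̂₁ (level order of the labels)."""
    d = np.where(codes == 1, 1.0 / counts[1], -1.0 / counts[0])
    return d


def diff_coordinates(gram: GramMatrix, labels, decomp: GramDecomposition) -> DiffCoordinates:
    """Coordinates of the mean-embedding difference on the within-PCA axes.

    Purely Gram-based: coords[t] = a_tᵀ P K d with d the signed group
    indicator giving Φ d = μ̂₂ − μ̂₁.
    """
    labels = _as_categorical(labels)
    codes, levels, counts = _group_index(labels)
    if len(levels) != 2:
        raise ValueError(
            f"diff_coordinates is two-sample ({len(levels)} conditions found); "
            "use the multigroup test instead"
        )
    d = mean_difference_vector(codes, counts)
    v = gram.values @ d
    Pv = _center_vector_within(v, codes, 2)
    coords = decomp.dual_coefficients.T @ Pv
    return DiffCoordinates(coords, int(counts[0]), int(counts[1]))


def batch_correct_gram(gram: GramMatrix, batch) -> GramMatrix:
    """Remove batch effects at the embedding level.

    Applies φ̃(Y) = φ(Y) − μ̂_{batch(Y)} + μ̂_overall in Gram coordinates
    — a non-linear normalization that equalizes the per-batch mean
    embeddings (after correction, every batch's mean embedding equals
    the overall one, so the between-batch MMD² vanishes).
    """
    batch = _as_categorical(batch)
    K = gram.values
    n = K.shape[0]
    if len(batch) != n:
        raise ValueError("batch labels do not match Gram size")
    codes, levels, counts = _group_index(batch)
    if counts.min() < 2:
        small = [levels[g] for g in np.flatnonzero(counts < 2)]
        raise ValueError(f"singleton batch(es) cannot be corrected: {small}")
    C = np.stack([K[:, codes == g].mean(axis=1) for g in range(len(levels))], axis=1)
    E = np.stack([C[codes == g].mean(axis=0) for g in range(len(levels))], axis=0)
    r = K.mean(axis=1)
    dbar = np.array([r[codes == g].mean() for g in range(len(levels))])
    gbar = r.mean()
    Kt = (
        K
        - C[:, codes]
        - C[:, codes].T
        + E[np.ix_(codes, codes)]
        + r[:, None]
        + r[None, :]
        - dbar[codes][:, None]
        - dbar[codes][None, :]
        + gbar
    )
    Kt = (Kt + Kt.T) / 2.0
    return GramMatrix(Kt, gram.kernel, list(gram.cell_order))
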