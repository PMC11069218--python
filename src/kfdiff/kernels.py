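"""Kernel functions, bandwidth calibration and Gram-matrix construction.

Three kernel families are supported:

* ``gauss`` — the Gaussian (RBF) kernel
  ``k(y, y') = exp(-||y - y'||² / (2σ²))`` with bandwidth σ calibrated
  by the median heuristic unless given explicitly.  Universal, hence
  testing equality of mean embeddings is equivalent to testing equality
  of distributions.
* ``linear`` — the standard scalar product; included to contrast the
  non-linear tests with their linear (Hotelling-type) counterpart.
* ``zi_gauss`` — a zero-inflated Gaussian probability-product kernel
  for sparse univariate count data: each observation is represented as
  a two-compartment density (point mass at zero with per-condition
  weight π, plus a Gaussian centred at the observed value), and the
  kernel is the L² inner product of the two densities.

Every constructor returns a :class:`GramMatrix`, which is symmetric and
positive semi-definite by construction and carries its
:class:`KernelSpec` for provenance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .dataset import Dataset

__all__ = [
    "KernelSpec",
    "GramMatrix",
    "DegenerateBandwidthError",
    "median_heuristic",
    "gauss_gram",
    "linear_gram",
    "zi_gauss_gram",
    "estimate_zero_proportions",
    "compute_gram",
    "zi_sigma_from_nonzero",
]

_FAMILIES = ("gauss", "zi_gauss", "linear")


class DegenerateBandwidthError(ValueError):
    """Raised when the median heuristic cannot produce a positive bandwidth."""


@dataclass(frozen=True)
class KernelSpec:
    """Everything needed to turn a Dataset into a Gram matrix.

    ``bandwidth`` may be a positive number (σ) or the sentinel string
    ``"median"`` meaning: calibrate by the median heuristic on the data
    the Gram is computed from.  For the zero-inflated Gaussian kernel,
    ``zero_inflation`` maps each condition level to its zero proportion
    π (per feature when used gene-wise) and ``zi_sigma`` is the scale of
    the Gaussian compartment; either may be left None to be estimated
    from the data.  ``zi_component`` selects the Gaussian-component
    convention: ``"product"`` (normalized probability-product form,
    default) or ``"results"`` (unnormalized exponential).
    """

    family: str = "gauss"
    bandwidth: float | str = "median"
    zero_inflation: dict | None = None
    zi_sigma: float | None = None
    zi_component: str = "product"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; expected one of {_FAMILIES}")
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "median":
                raise ValueError("bandwidth must be a positive number or 'median'")
        elif not (np.isfinite(self.bandwidth) and self.bandwidth > 0):
            raise ValueError(f"bandwidth must be strictly positive and finite, got {self.bandwidth}")
        if self.zero_inflation is not None:
            if self.family != "zi_gauss":
                raise ValueError("zero_inflation only applies to the zi_gauss family")
            for cond, pi in self.zero_inflation.items():
                arr = np.asarray(pi, dtype=float)
                if np.any((arr < 0) | (arr > 1)):
                    raise ValueError(f"zero proportion for condition {cond!r} outside [0, 1]")
        if self.zi_sigma is not None and not self.zi_sigma > 0:
            raise ValueError("zi_sigma must be strictly positive")
        if self.zi_component not in ("product", "results"):
            raise ValueError("zi_component must be 'product' or 'results'")

    def resolve_bandwidth(self, data: Dataset) -> "KernelSpec":
        """Replace the 'median' sentinel by the calibrated σ."""
        if self.bandwidth == "median":
            return replace(self, bandwidth=math.sqrt(median_heuristic(data)))
        return self


@dataclass
class GramMatrix:
    """Symmetric PSD similarity matrix with its kernel provenance."""

    values: np.ndarray
    kernel: KernelSpec
    cell_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("Gram matrix must be square")
        if not self.cell_order:
            self.cell_order = [f"c{j}" for j in range(n)]
        if len(self.cell_order) != n:
            raise ValueError("cell_order length does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def check(self, tol: float = 1e-8) -> None:
        """Assert symmetry and positive semi-definiteness within tolerance."""
        K = self.values
        scale = max(np.abs(K).max(), 1.0)
        if np.abs(K - K.T).max() > tol * scale:
            raise ValueError("Gram matrix is not symmetric within tolerance")
        w = np.linalg.eigvalsh((K + K.T) / 2)
        if w.min() < -tol * max(w.max(), 1.0):
            raise ValueError(f"Gram matrix not PSD: min eigenvalue {w.min():.3g}")


# ---------------------------------------------------------------------------
# bandwidth calibration
# ---------------------------------------------------------------------------

def median_heuristic(data: Dataset) -> float:
    """Median of squared Euclidean distances over distinct cell pairs.

    Cells from all conditions are pooled; self-pairs are excluded.  The
    returned value is σ² (the Gaussian kernel uses its square root as
    bandwidth).  When the median itself is zero — common for sparse
    count genes where most pairs are zero–zero ties — but positive
    distances exist, the median of the strictly positive squared
    distances is used instead (with a warning); if every pairwise
    distance is zero a :class:`DegenerateBandwidthError` is raised.
    """
    if data.n_cells < 2:
        raise ValueError("median heuristic needs at least 2 cells")
    d2 = pdist(data.values, metric="sqeuclidean")
    med = float(np.median(d2))
    if med > 0:
        return med
    positive = d2[d2 > 0]
    if positive.size == 0:
        raise DegenerateBandwidthError(
            "all cells are identical: the median pairwise distance is 0; "
            "supply the bandwidth σ explicitly"
        )
    warnings.warn(
        "median pairwise distance is 0 (ties dominate); falling back to the "
        "median of strictly positive distances",
        RuntimeWarning,
        stacklevel=2,
    )
    return float(np.median(positive))


# ---------------------------------------------------------------------------
# Gram constructors
# ---------------------------------------------------------------------------

def gauss_gram(data: Dataset, spec: KernelSpec) -> GramMatrix:
    """Gaussian kernel Gram: entry (a,b) = exp(−‖y_a − y_b‖²/(2σ²))."""
    if spec.family != "gauss":
        raise ValueError(f"expected a gauss KernelSpec, got family {spec.family!r}")
    spec = spec.resolve_bandwidth(data)
    sigma = float(spec.bandwidth)
    d2 = squareform(pdist(data.values, metric="sqeuclidean"))
    K = np.exp(-d2 / (2.0 * sigma**2))
    np.fill_diagonal(K, 1.0)
    return GramMatrix(K, spec, list(data.cell_ids))


def linear_gram(data: Dataset) -> GramMatrix:
    """Scalar-product Gram: entry (a,b) = Σ_g y_a[g]·y_b[g]."""
    K = data.values @ data.values.T
    K = (K + K.T) / 2.0
    return GramMatrix(K, KernelSpec(family="linear", bandwidth=1.0), list(data.cell_ids))


def estimate_zero_proportions(data: Dataset, feature: str | None = None) -> pd.Series:
    """Per-condition zero proportion π_i = #zeros / n_i for one feature.

    With ``feature=None`` the dataset must be univariate.
    """
    sub = data if feature is None else data.feature(feature)
    if sub.n_features != 1:
        raise ValueError("zero proportions are defined per feature; name one")
    col = sub.values[:, 0]
    out = {}
    for level, idx in sub.group_indices().items():
        out[level] = float(np.mean(col[idx] == 0))
    return pd.Series(out, name="pi")


def zi_sigma_from_nonzero(data: Dataset) -> float:
    """Scale of the Gaussian compartment: median distance between the
    non-zero observations (univariate)."""
    if data.n_features != 1:
        raise ValueError("zi_sigma calibration is univariate")
    nz = data.values[data.values[:, 0] != 0, 0]
    if nz.size < 2:
        raise DegenerateBandwidthError(
            "fewer than two non-zero observations: cannot calibrate zi_sigma"
        )
    diffs = pdist(nz[:, None], metric="euclidean")
    med = float(np.median(diffs))
    if med == 0:
        positive = diffs[diffs > 0]
        if positive.size == 0:
            raise DegenerateBandwidthError("all non-zero observations identical")
        med = float(np.median(positive))
    return med


def zi_gauss_gram(data: Dataset, spec: KernelSpec) -> GramMatrix:
    """Zero-inflated Gaussian probability-product Gram (univariate).

    Cell (i,j) with observed value μ in condition i is represented by
    the density π_i·δ₀ + (1−π_i)·f_{μ,σ}; the kernel between two cells
    is the inner product of their densities:

        π_i π_i' + π_i(1−π_i') f_{μ',σ}(0) + (1−π_i) π_i' f_{μ,σ}(0)
        + (1−π_i)(1−π_i') k_component(μ, μ')

    where the Gaussian-component term is, by default, the
    probability-product kernel (1/4πσ²)·exp(−(μ−μ')²/4σ²); the
    ``zi_component="results"`` convention uses the unnormalized
    exp(−(μ−μ')²/2σ²) instead.  σ defaults to the median distance
    between non-zero observations, and π to the empirical per-condition
    zero proportions.
    """
    if spec.family != "zi_gauss":
        raise ValueError(f"expected a zi_gauss KernelSpec, got family {spec.family!r}")
    if data.n_features != 1:
        raise ValueError(
            "the zero-inflated Gaussian kernel is defined for univariate "
            "(per-feature) testing only"
        )
    levels = data.condition_levels
    if spec.zero_inflation is None:
        pi_table = estimate_zero_proportions(data).to_dict()
    else:
        pi_table = {k: float(np.asarray(v).reshape(())) for k, v in spec.zero_inflation.items()}
        missing = [lv for lv in levels if lv not in pi_table]
        if missing:
            raise ValueError(f"zero_inflation lacks condition level(s) {missing}")
    for lv, pi in pi_table.items():
        if not 0.0 <= pi <= 1.0:
            raise ValueError(f"zero proportion for {lv!r} outside [0, 1]: {pi}")

    sigma = spec.zi_sigma if spec.zi_sigma is not None else zi_sigma_from_nonzero(data)
    spec = replace(
        spec,
        zero_inflation={k: pi_table[k] for k in levels},
        zi_sigma=float(sigma),
        bandwidth=float(sigma),
    )

    mu = data.values[:, 0]
    codes = data.condition.cat.codes.to_numpy()
    pi = np.array([pi_table[levels[c]] for c in codes])

    f0 = np.exp(-(mu**2) / (2.0 * sigma**2)) / (sigma * math.sqrt(2.0 * math.pi))
    diff2 = (mu[:, None] - mu[None, :]) ** 2
    if spec.zi_component == "product":
        comp = np.exp(-diff2 / (4.0 * sigma**2)) / (4.0 * math.pi * sigma**2)
    else:
        comp = np.exp(-diff2 / (2.0 * sigma**2))

    P, Q = pi[:, None], pi[None, :]
    K = P * Q + P * (1 - Q) * f0[None, :] + (1 - P) * Q * f0[:, None] + (1 - P) * (1 - Q) * comp
    K = (K + K.T) / 2.0
    return GramMatrix(K, spec, list(data.cell_ids))


def compute_gram(data: Dataset, spec: KernelSpec) -> GramMatrix:
    """Dispatch on the kernel family."""
    if spec.family == "gauss":
        return gauss_gram(data, spec)
    if spec.family == "linear":
        return linear_gram(data)
    return zi_gauss_gram(data, spec)


def cross_gram(data_a: Dataset, data_b: Dataset, spec: KernelSpec) -> np.ndarray:
    """Rectangular kernel matrix k(a, b) between two cell sets.

    Requires a fully resolved spec (numeric bandwidth; for zi_gauss, an
    explicit zero-proportion table and zi_sigma) so both blocks are
    evaluated with identical parameters — used by the Nystrom landmark
    feature map.
    """
    from scipy.spatial.distance import cdist

    if spec.family == "linear":
        return data_a.values @ data_b.values.T
    if spec.family == "gauss":
        if isinstance(spec.bandwidth, str):
            raise ValueError("cross_gram needs a resolved (numeric) bandwidth")
        d2 = cdist(data_a.values, data_b.values, metric="sqeuclidean")
        return np.exp(-d2 / (2.0 * float(spec.bandwidth) ** 2))
    if spec.zero_inflation is None or spec.zi_sigma is None:
        raise ValueError("cross_gram needs explicit zero_inflation and zi_sigma for zi_gauss")
    if data_a.n_features != 1 or data_b.n_features != 1:
        raise ValueError("the zero-inflated Gaussian kernel is univariate")
    sigma = float(spec.zi_sigma)
    mu_a, mu_b = data_a.values[:, 0], data_b.values[:, 0]
    pi_a = np.array([spec.zero_inflation[lv] for lv in data_a.condition])
    pi_b = np.array([spec.zero_inflation[lv] for lv in data_b.condition])
    f0a = np.exp(-(mu_a**2) / (2.0 * sigma**2)) / (sigma * math.sqrt(2.0 * math.pi))
    f0b = np.exp(-(mu_b**2) / (2.0 * sigma**2)) / (sigma * math.sqrt(2.0 * math.pi))
    diff2 = (mu_a[:, None] - mu_b[None, :]) ** 2
    if spec.zi_component == "product":
        comp = np.exp(-diff2 / (4.0 * sigma**2)) / (4.0 * math.pi * sigma**2)
    else:
        comp = np.exp(-diff2 / (2.0 * sigma**2))
    P, Q = pi_a[:, None], pi_b[None, :]
    return P * Q + P * (1 - Q) * f0b[None, :] + (1 - P) * Q * f0a[:, None] + (1 - P) * (1 - Q) * comp
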