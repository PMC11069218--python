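"""Discriminant axis, per-cell projections and diagnostic coordinates.

The truncated Fisher discriminant axis

    h*_T ∝ Σ_{t≤T} (⟨ê_t, μ̂₂ − μ̂₁⟩ / λ̂_t) · ê_t,   ‖h*_T‖ = 1,

is the feature-space direction maximizing the (truncated) Fisher
discriminant ratio; the ratio's maximal value is exactly the test
statistic D̂²_T.  Projecting cells onto h*_T is a non-linear transform
of the raw data under which the two conditions become linearly
separable whenever the kernel detects a difference — cells at the
extremes of the axis carry the discriminating signal, cells near the
center are uninformative.  Projections on the within-covariance
principal components (kernel PCA of condition-centered expression)
complete the diagnostic picture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embedding import (
    DiffCoordinates,
    GramDecomposition,
    _as_categorical,
    _center_vector_within,
    _group_index,
)
from .kernels import GramMatrix

__all__ = [
    "DiscriminantAxis",
    "discriminant_axis",
    "project_cells",
    "project_on_pc",
    "projection_frame",
    "plot_projection",
]


class UndefinedAxisError(ValueError):
    """The two mean embeddings coincide: no discriminant direction exists."""


@dataclass
class DiscriminantAxis:
    """Unit-norm discriminant direction in dual coordinates.

    ``basis_coefficients`` express h*_T in the orthonormal ê_t basis;
    ``dual_coefficients`` express it over the condition-centered
    embeddings (h*_T = Σ_j w_j (φ(Y_j) − μ̂_{cond(j)})).
    """

    basis_coefficients: np.ndarray
    dual_coefficients: np.ndarray
    truncation: int


def discriminant_axis(decomp: GramDecomposition, diff: DiffCoordinates) -> DiscriminantAxis:
    """Closed-form maximizer of the truncated Fisher discriminant ratio."""
    lam = decomp.eigenvalues
    if decomp.T == 0:
        raise UndefinedAxisError("empty spectrum: no discriminant direction")
    c = diff.coords / lam
    norm = np.linalg.norm(c)
    # relative numerical-zero test: the mean-difference coordinates live on
    # the √λ scale, so compare against it
    if not np.isfinite(norm) or np.all(np.abs(diff.coords) < 1e-9 * np.sqrt(lam)):
        raise UndefinedAxisError(
            "the two mean embeddings coincide (identical samples): axis undefined"
        )
    c = c / norm
    return DiscriminantAxis(
        basis_coefficients=c,
        dual_coefficients=decomp.dual_coefficients @ c,
        truncation=decomp.T,
    )


def project_cells(gram: GramMatrix, labels, axis: DiscriminantAxis) -> pd.DataFrame:
    """Per-cell scores ⟨φ(Y) − μ̂_pooled, h*_T⟩.

    Scores are centered at 0 across all cells (pooled-mean offset) and
    oriented so the second condition level has the larger mean score.
    """
    labels = _as_categorical(labels)
    codes, levels, _ = _group_index(labels)
    n_groups = len(levels)
    Pw = _center_vector_within(axis.dual_coefficients, codes, n_groups)
    scores = gram.values @ Pw
    scores = scores - scores.mean()
    if n_groups == 2 and scores[codes == 1].mean() < scores[codes == 0].mean():
        scores = -scores
    return pd.DataFrame(
        {"cell_id": list(gram.cell_order), "condition": labels.astype(str).to_numpy(),
         "score": scores}
    )


def project_on_pc(gram: GramMatrix, decomp: GramDecomposition, t: int) -> np.ndarray:
    """Kernel-PCA coordinate of every cell on the t-th eigenfunction ê_t.

    1-based t.  Coordinates are centered by the pooled mean; their
    pooled within-condition (biased) variance equals λ_t.
    """
    if not 1 <= t <= decomp.T:
        raise ValueError(f"t={t} out of range 1..{decomp.T}")
    codes, levels, _ = _group_index(decomp.labels)
    Pa = _center_vector_within(decomp.dual_coefficients[:, t - 1], codes, len(levels))
    z = gram.values @ Pa
    return z - z.mean()


def projection_frame(
    gram: GramMatrix,
    labels,
    decomp: GramDecomposition,
    diff: DiffCoordinates,
    batch=None,
    n_pcs: int | None = None,
) -> pd.DataFrame:
    """Assemble the full diagnostic table: score + PC coordinates."""
    axis = discriminant_axis(decomp, diff)
    frame = project_cells(gram, labels, axis)
    if batch is not None:
        frame.insert(2, "batch", pd.Series(np.asarray(batch)).astype(str).to_numpy())
    n_pcs = decomp.T if n_pcs is None else min(n_pcs, decomp.T)
    for t in range(1, n_pcs + 1):
        frame[f"pc{t}"] = project_on_pc(gram, decomp, t)
    return frame


def plot_projection(frame: pd.DataFrame, path: str, by: str = "condition") -> None:
    """Density plot of discriminant scores per group (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for level, sub in frame.groupby(by, observed=True):
        ax.hist(sub["score"], bins=40, density=True, alpha=0.5, label=str(level))
    ax.set_xlabel("discriminant-axis score")
    ax.set_ylabel("density")
    ax.legend(title=by)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
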