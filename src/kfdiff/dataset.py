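"""Cells × features container shared by every kernel-testing routine.

A :class:`Dataset` holds a dense numeric matrix (cells as rows), a
per-cell condition label (the groups being compared) and an optional
per-cell batch label.  It is deliberately lighter than an ``AnnData``:
the testing pipeline only ever needs the matrix and the two label
vectors, and keeping the container minimal makes the Gram-space
algebra easy to audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset"]


@dataclass
class Dataset:
    """Expression (or binned-coverage) matrix with condition/batch labels.

    Parameters
    ----------
    values
        ``(n_cells, n_features)`` real matrix, dense, no missing values.
    condition
        Length-``n_cells`` categorical label; testing requires at least
        two levels, each with at least two cells.
    batch
        Optional length-``n_cells`` categorical label for batch
        correction.
    feature_names
        Feature identifiers; defaults to ``f0, f1, ...``.
    cell_ids
        Cell identifiers; defaults to ``c0, c1, ...``.
    """

    values: np.ndarray
    condition: pd.Series
    batch: pd.Series | None = None
    feature_names: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d cells × features matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN or infinite entries")
        n = self.values.shape[0]
        self.condition = pd.Series(np.asarray(self.condition), name="condition").astype("category")
        if len(self.condition) != n:
            raise ValueError(
                f"condition has length {len(self.condition)}, expected {n} (one per cell)"
            )
        if self.batch is not None:
            self.batch = pd.Series(np.asarray(self.batch), name="batch").astype("category")
            if len(self.batch) != n:
                raise ValueError(f"batch has length {len(self.batch)}, expected {n}")
        if not self.feature_names:
            self.feature_names = [f"f{g}" for g in range(self.values.shape[1])]
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length does not match the number of columns")
        if not self.cell_ids:
            self.cell_ids = [f"c{j}" for j in range(n)]
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match the number of rows")

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def condition_levels(self) -> list:
        return list(self.condition.cat.categories)

    def group_sizes(self) -> dict:
        return self.condition.value_counts().reindex(self.condition_levels).to_dict()

    def group_indices(self) -> dict:
        """Row indices per condition level, in level order."""
        codes = self.condition.cat.codes.to_numpy()
        return {
            level: np.flatnonzero(codes == k)
            for k, level in enumerate(self.condition_levels)
        }

    def require_groups(self, min_levels: int = 2, min_cells: int = 2) -> None:
        sizes = self.group_sizes()
        if len(sizes) < min_levels:
            raise ValueError(
                f"need at least {min_levels} condition levels, found {len(sizes)}"
            )
        small = {k: v for k, v in sizes.items() if v < min_cells}
        if small:
            raise ValueError(f"each condition needs ≥{min_cells} cells; too small: {small}")

    def feature(self, name: str) -> "Dataset":
        """Univariate view of a single feature (used by gene-wise tests)."""
        try:
            g = self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None
        return Dataset(
            self.values[:, [g]],
            self.condition,
            batch=self.batch,
            feature_names=[name],
            cell_ids=self.cell_ids,
        )

    def subset(self, rows: np.ndarray) -> "Dataset":
        rows = np.asarray(rows)
        return Dataset(
            self.values[rows],
            self.condition.iloc[rows].reset_index(drop=True),
            batch=None if self.batch is None else self.batch.iloc[rows].reset_index(drop=True),
            feature_names=self.feature_names,
            cell_ids=[self.cell_ids[j] for j in rows],
        )

    def with_condition(self, condition) -> "Dataset":
        """Same matrix under different labels (permutation tests)."""
        return Dataset(
            self.values,
            pd.Series(np.asarray(condition)),
            batch=self.batch,
            feature_names=self.feature_names,
            cell_ids=self.cell_ids,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.feature_names)
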