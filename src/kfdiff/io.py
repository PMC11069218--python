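"""Readers and writers for the delimited-text and MatrixMarket dialects.

Counts come either as a dense TSV/CSV (cells × features, header row of
feature names, index column of cell IDs) or as a MatrixMarket ``.mtx``
with sidecar feature/cell ID files (one identifier per line).  The
single-cell MTX convention stores genes × cells; pass
``transpose=True`` to flip it.  Cell metadata is a TSV with columns
``cell_id``, ``condition`` and optionally ``batch``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .dataset import Dataset

__all__ = [
    "read_counts_table",
    "read_counts_mtx",
    "read_metadata",
    "assemble_dataset",
    "write_counts_table",
    "write_metadata",
    "write_manifest",
]


def read_counts_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Dense counts table; separator inferred from the suffix unless given."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # surface file + cause, per the CLI contract
        raise ValueError(f"malformed counts table {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"malformed counts table {path}: no feature columns found")
    return df


def read_counts_mtx(
    path: str | Path,
    features: str | Path,
    cells: str | Path,
    transpose: bool = False,
) -> pd.DataFrame:
    """MatrixMarket matrix with sidecar ID files.

    ``transpose=True`` treats the stored matrix as genes × cells (the
    usual single-cell layout) and returns cells × features.
    """
    mat = scipy.io.mmread(str(path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    if transpose:
        mat = mat.T
    feat_ids = _read_id_file(features)
    cell_ids = _read_id_file(cells)
    if mat.shape != (len(cell_ids), len(feat_ids)):
        raise ValueError(
            f"matrix {path} is {mat.shape} but sidecars give "
            f"{len(cell_ids)} cells × {len(feat_ids)} features "
            "(is --transpose set correctly?)"
        )
    return pd.DataFrame(mat, index=cell_ids, columns=feat_ids)


def _read_id_file(path: str | Path) -> list[str]:
    with open(path) as fh:
        ids = [line.strip().split("\t")[0] for line in fh if line.strip()]
    if not ids:
        raise ValueError(f"empty identifier file {path}")
    return ids


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"cell_id", "condition"} - set(meta.columns)
    if missing:
        raise ValueError(f"metadata {path} lacks required column(s): {sorted(missing)}")
    return meta


def assemble_dataset(counts: pd.DataFrame, meta: pd.DataFrame) -> Dataset:
    """Align a counts table with its metadata on cell_id."""
    meta = meta.set_index("cell_id")
    missing = [c for c in counts.index if c not in meta.index]
    if missing:
        raise ValueError(f"{len(missing)} cells absent from metadata (e.g. {missing[:3]})")
    meta = meta.loc[counts.index]
    return Dataset(
        counts.to_numpy(dtype=float),
        pd.Series(meta["condition"].to_numpy()),
        batch=pd.Series(meta["batch"].to_numpy()) if "batch" in meta.columns else None,
        feature_names=[str(c) for c in counts.columns],
        cell_ids=[str(c) for c in counts.index],
    )


def write_counts_table(data: Dataset, path: str | Path) -> None:
    data.to_dataframe().to_csv(path, sep="\t", index_label="cell_id")


def write_metadata(data: Dataset, path: str | Path) -> None:
    meta = pd.DataFrame({"cell_id": data.cell_ids, "condition": data.condition.astype(str)})
    if data.batch is not None:
        meta["batch"] = data.batch.astype(str).to_numpy()
    meta.to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
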