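"""CSV/TSV readers and writers for expression matrices and sweep results.

File layout: header row of feature IDs, first column of sample IDs,
optional ``label`` column for class labels. Missing entries in test
files are empty cells or ``NA``; alternatively a separate 0/1 mask file
of the same shape can be supplied. Delimiter is sniffed from the
extension (.csv / .tsv) unless given explicitly.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DuplicateIdError, InvalidInputError
from .types import ExpressionMatrix, MaskedProfile

LABEL_COLUMN = "label"


def _delimiter(path: Path, dialect: str | None) -> str:
    if dialect in ("csv", ","):
        return ","
    if dialect in ("tsv", "\t"):
        return "\t"
    if dialect is not None:
        raise InvalidInputError(f"unknown dialect {dialect!r}")
    return "\t" if path.suffix.lower() == ".tsv" else ","


def read_matrix(
    path: str | Path, dialect: str | None = None
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Read a samples x features matrix; returns (matrix, missing mask).

    NA or empty cells are recorded as True in the returned boolean mask
    (and as NaN in the matrix values). An optional ``label`` column is
    read into ``labels``.
    """
    path = Path(path)
    sep = _delimiter(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"], keep_default_na=True)
    if df.index.has_duplicates:
        raise DuplicateIdError("duplicate-id: repeated sample identifiers")
    if df.columns.has_duplicates:
        raise DuplicateIdError("duplicate-id: repeated feature identifiers")
    labels = None
    if LABEL_COLUMN in df.columns:
        labels = df[LABEL_COLUMN].to_numpy()
        df = df.drop(columns=[LABEL_COLUMN])
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as e:
        raise InvalidInputError(f"non-numeric cell in {path}: {e}") from e
    mask = np.isnan(values)
    em = ExpressionMatrix(
        values=values,
        sample_ids=[str(i) for i in df.index],
        feature_ids=[str(c) for c in df.columns],
        labels=labels,
    )
    return em, mask


def read_mask(path: str | Path, dialect: str | None = None) -> np.ndarray:
    """Read a 0/1 mask file (same layout as the matrix, 1 = missing)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path, dialect), index_col=0)
    return df.to_numpy(dtype=float) > 0.5


def to_profiles(em: ExpressionMatrix, mask: np.ndarray) -> list[MaskedProfile]:
    """Split a matrix + mask into per-sample masked profiles."""
    if mask.shape != em.values.shape:
        raise InvalidInputError("mask shape must match matrix shape")
    vals = np.where(mask, 0.0, em.values)  # masked entries are ignored downstream
    return [
        MaskedProfile(values=vals[i], mask=mask[i], sample_id=em.sample_ids[i])
        for i in range(em.n_samples)
    ]


def write_matrix(em: ExpressionMatrix, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(em.values, index=em.sample_ids, columns=em.feature_ids)
    if em.labels is not None:
        df[LABEL_COLUMN] = em.labels
    df.to_csv(path, sep=_delimiter(path, dialect), index_label="sample_id")


def write_results(
    completed: ExpressionMatrix | None,
    sweep: pd.DataFrame | None,
    summary: pd.DataFrame | None,
    out_dir: str | Path,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write run outputs: completed matrix, sweep and summary CSVs, and a
    JSON manifest (config + seeds + versions) for reproducibility."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if completed is not None:
        p = out_dir / "completed.csv"
        write_matrix(completed, p)
        written["completed"] = p
    if sweep is not None:
        p = out_dir / "sweep.csv"
        sweep.to_csv(p, index=False)
        written["sweep"] = p
    if summary is not None:
        p = out_dir / "summary.csv"
        summary.to_csv(p, index=False)
        written["summary"] = p
    meta = dict(manifest or {})
    meta.setdefault("python", sys.version.split()[0])
    meta.setdefault("numpy", np.__version__)
    meta.setdefault("pandas", pd.__version__)
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    written["manifest"] = p
    return written
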