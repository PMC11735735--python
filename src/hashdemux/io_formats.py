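"""Reading and writing tag-by-cell count matrices and label tables.

Two on-disk matrix layouts are supported:

* a CellRanger-style directory holding ``matrix.mtx``, ``features.tsv`` and
  ``barcodes.tsv`` (each optionally gzipped), features (tags) x cells;
* a dense delimited text file with tags as rows, cells as columns, and a
  header row of cell barcodes.

Label tables (predictions or ground truth) are CSV files with columns
``barcode,label,confidence``, where each label is one of the tag names,
``"Doublet"`` or ``"Negative"``.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

DOUBLET = "Doublet"
NEGATIVE = "Negative"

MTX_NAMES = ("matrix.mtx", "features.tsv", "barcodes.tsv")


class FormatError(ValueError):
    """A file is missing or cannot be parsed as the expected format."""


class ValidationError(ValueError):
    """Parsed data violate a contract (shapes, duplicates, negative counts)."""


@dataclass
class TagCountMatrix:
    """Raw tag counts: an integer matrix of M tags x N cells.

    Attributes
    ----------
    counts
        ``(M, N)`` array of non-negative integers; ``counts[i, j]`` is the
        number of reads of tag *i* in cell *j*.
    tag_names
        M unique tag names (rows).
    barcodes
        N unique cell barcodes (columns).
    """

    counts: np.ndarray
    tag_names: list[str] = field(default_factory=list)
    barcodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix (tags x cells)")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("tag counts must be integral")
            counts = np.round(counts).astype(np.int64)
        self.counts = counts.astype(np.int64, copy=False)
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("tag counts must be non-negative")
        self.tag_names = [str(t) for t in self.tag_names]
        self.barcodes = [str(b) for b in self.barcodes]
        m, n = self.counts.shape
        if len(self.tag_names) != m:
            raise ValidationError(
                f"{len(self.tag_names)} tag names for {m} matrix rows"
            )
        if len(self.barcodes) != n:
            raise ValidationError(
                f"{len(self.barcodes)} barcodes for {n} matrix columns"
            )
        if len(set(self.tag_names)) != m:
            raise ValidationError("duplicate tag names")
        if len(set(self.barcodes)) != n:
            raise ValidationError("duplicate barcodes")
        if m < 2:
            raise ValidationError("demultiplexing needs at least 2 tags")

    @property
    def n_tags(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def label_vocabulary(self) -> set[str]:
        """Valid assignment labels: tag names plus Doublet and Negative."""
        return set(self.tag_names) | {DOUBLET, NEGATIVE}


def _find(path: Path, stem: str) -> Path:
    for cand in (path / stem, path / (stem + ".gz")):
        if cand.exists():
            return cand
    raise FormatError(f"missing {stem}[.gz] in {path}")


def _read_table(path: Path) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return pd.read_csv(fh, sep="\t", header=None, dtype=str)


def read_mtx_dir(path: str | Path) -> TagCountMatrix:
    """Read a Matrix Market directory (matrix.mtx + features.tsv + barcodes.tsv).

    The matrix on disk is oriented features (tags) x cells; feature and
    barcode order is preserved. Gzipped members are detected by extension.
    """
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"not a directory: {path}")
    mtx_path = _find(path, "matrix.mtx")
    try:
        if mtx_path.suffix == ".gz":
            with gzip.open(mtx_path, "rb") as fh:
                mat = scipy.io.mmread(fh)
        else:
            mat = scipy.io.mmread(mtx_path)
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    dense = np.asarray(
        mat.todense() if scipy.sparse.issparse(mat) else mat
    )
    if dense.size and not np.allclose(dense, np.round(dense)):
        raise ValidationError("matrix contains non-integer entries")
    if dense.size and dense.min() < 0:
        raise ValidationError("matrix contains negative entries")
    features = _read_table(_find(path, "features.tsv"))
    barcodes = _read_table(_find(path, "barcodes.tsv"))
    tag_names = features.iloc[:, 0].tolist()
    bc = barcodes.iloc[:, 0].tolist()
    if len(tag_names) != dense.shape[0] or len(bc) != dense.shape[1]:
        raise ValidationError(
            f"matrix is {dense.shape} but found {len(tag_names)} features "
            f"and {len(bc)} barcodes"
        )
    return TagCountMatrix(dense.astype(np.int64), tag_names, bc)


def write_mtx_dir(matrix: TagCountMatrix, path: str | Path) -> Path:
    """Write a TagCountMatrix as a CellRanger-style MTX directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        path / "matrix.mtx", scipy.sparse.coo_matrix(matrix.counts)
    )
    pd.Series(matrix.tag_names).to_csv(
        path / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(matrix.barcodes).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    return path


def _sep_for(path: Path) -> str:
    name = path.name[:-3] if path.suffix == ".gz" else path.name
    return "," if name.endswith(".csv") else "\t"


def read_dense(path: str | Path) -> TagCountMatrix:
    """Read a dense delimited matrix: header row = barcodes, first column = tags."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sep = _sep_for(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(header) != len(set(header)):  # pandas would mangle duplicates
        raise ValidationError("duplicate barcodes in header")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.index.duplicated().any():
        raise ValidationError("duplicate tag names")
    values = df.to_numpy()
    if values.dtype == object or np.isnan(np.asarray(values, dtype=float)).any():
        raise FormatError("ragged or non-numeric rows")
    return TagCountMatrix(
        np.asarray(values), df.index.tolist(), [str(c) for c in df.columns]
    )


def write_dense(matrix: TagCountMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        matrix.counts, index=matrix.tag_names, columns=matrix.barcodes
    )
    df.to_csv(path, sep=_sep_for(path))
    return path


LABEL_COLUMNS = ["barcode", "label", "confidence"]


def as_label_table(obj) -> pd.DataFrame:
    """Coerce a DemuxResult or DataFrame into a label table DataFrame."""
    if hasattr(obj, "to_label_table"):
        return obj.to_label_table()
    df = pd.DataFrame(obj)
    if "confidence" not in df.columns:
        df = df.assign(confidence=np.nan)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"label table missing columns: {missing}")
    return df[LABEL_COLUMNS].copy()


def write_labels(result, path: str | Path, vocabulary: set[str] | None = None) -> Path:
    """Write per-cell labels to CSV (columns barcode,label,confidence).

    If ``vocabulary`` is given, any label outside it raises ValidationError.
    """
    table = as_label_table(result)
    if table["barcode"].duplicated().any():
        raise ValidationError("duplicate barcodes in label table")
    if vocabulary is not None:
        bad = set(table["label"]) - set(vocabulary)
        if bad:
            raise ValidationError(f"labels outside vocabulary: {sorted(bad)}")
    conf = pd.to_numeric(table["confidence"], errors="coerce")
    if ((conf < 0) | (conf > 1)).any():
        raise ValidationError("confidence values must lie in [0, 1]")
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_labels(path: str | Path, vocabulary: set[str] | None = None) -> pd.DataFrame:
    """Read a barcode,label,confidence CSV written by :func:`write_labels`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"barcode": str, "label": str})
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"label table missing columns: {missing}")
    if df["barcode"].duplicated().any():
        raise ValidationError("duplicate barcodes in label table")
    if vocabulary is not None:
        bad = set(df["label"]) - set(vocabulary)
        if bad:
            raise ValidationError(f"labels outside vocabulary: {sorted(bad)}")
    return df[LABEL_COLUMNS]
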