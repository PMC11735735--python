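"""Normalization of hashtag count matrices.

Four methods are provided, all operating on the raw M x N tag-count matrix
``r`` (tags x cells) and returning a real-valued matrix of identical shape.
``log`` is the natural logarithm throughout.

* ``lognorm``        n_ij = log(r_ij * scale / S_j + 1), S_j the per-cell total
* ``rc``             n_ij = r_ij * scale / S_j
* ``clr_exp_bias``   n_ij = log(r_ij / G_i + 1), G_i a per-tag geometric mean
                     (removes tag-specific baseline / ambient bias)
* ``clr_seq_depth``  n_ij = log(r_ij / G_j + 1), G_j a per-cell geometric mean
                     (removes per-cell sequencing-depth variability)

Tag counts contain zeros, so the geometric means use a pseudocount of one:
G = exp(mean(log(1 + r))) over the row (per tag) or column (per cell). This is
defined for zero counts and approaches the plain geometric mean for large
counts.

Cells with a zero total (S_j = 0) cannot be depth-normalized; ``lognorm`` and
``rc`` set all their values to 0 and emit a warning (such empty droplets are
labeled Negative downstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import TagCountMatrix

DEFAULT_SCALE = 1e4

METHODS = ("lognorm", "rc", "clr_exp_bias", "clr_seq_depth")


@dataclass
class NormalizedTagMatrix:
    """Normalized tag values with the same shape and name order as the source.

    ``values[i, j]`` is the normalized count of tag *i* in cell *j*;
    ``method`` records which transform produced it and ``scale_factor`` the
    scale used by ``lognorm``/``rc`` (ignored by the CLR variants).
    """

    values: np.ndarray
    tag_names: list[str]
    barcodes: list[str]
    method: str
    scale_factor: float = DEFAULT_SCALE

    @property
    def n_tags(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def _cell_totals(R: TagCountMatrix) -> np.ndarray:
    totals = R.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        warnings.warn(
            f"{int((totals == 0).sum())} cell(s) have zero total tag counts; "
            "their normalized values are set to 0",
            stacklevel=3,
        )
    return totals


def log_normalize(R: TagCountMatrix, scale: float = DEFAULT_SCALE) -> NormalizedTagMatrix:
    """Depth-normalize then log-transform: n = log(r * scale / S_j + 1)."""
    totals = _cell_totals(R)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(totals > 0, R.counts * scale / totals, 0.0)
    return NormalizedTagMatrix(
        np.log1p(ratio), list(R.tag_names), list(R.barcodes), "lognorm", scale
    )


def relative_counts(R: TagCountMatrix, scale: float = DEFAULT_SCALE) -> NormalizedTagMatrix:
    """Counts as a fraction of the cell total, rescaled: n = r * scale / S_j."""
    totals = _cell_totals(R)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(totals > 0, R.counts * scale / totals, 0.0)
    return NormalizedTagMatrix(
        values, list(R.tag_names), list(R.barcodes), "rc", scale
    )


def _pseudo_geometric_mean(x: np.ndarray, axis: int) -> np.ndarray:
    # exp(mean(log(1 + x))): finite for zero counts, ~geometric mean for large x
    return np.exp(np.mean(np.log1p(x), axis=axis))


def clr_per_tag(R: TagCountMatrix) -> NormalizedTagMatrix:
    """Centered log-ratio across cells within each tag: n = log(r / G_i + 1).

    G_i is the (pseudocount-1) geometric mean of tag i over all cells. The
    transform is strictly increasing within each tag row, so per-tag rankings
    of cells — and hence per-tag separability — are unchanged.
    """
    g = _pseudo_geometric_mean(R.counts, axis=1)
    values = np.log1p(R.counts / g[:, None])
    return NormalizedTagMatrix(
        values, list(R.tag_names), list(R.barcodes), "clr_exp_bias"
    )


def clr_per_cell(R: TagCountMatrix) -> NormalizedTagMatrix:
    """Centered log-ratio across tags within each cell: n = log(r / G_j + 1).

    G_j is the (pseudocount-1) geometric mean of all tags in cell j; dividing
    by it removes per-cell sequencing-depth variability.
    """
    g = _pseudo_geometric_mean(R.counts, axis=0)
    values = np.log1p(R.counts / g[None, :])
    return NormalizedTagMatrix(
        values, list(R.tag_names), list(R.barcodes), "clr_seq_depth"
    )


_DISPATCH = {
    "lognorm": log_normalize,
    "rc": relative_counts,
    "clr_exp_bias": lambda R, scale=DEFAULT_SCALE: clr_per_tag(R),
    "clr_seq_depth": lambda R, scale=DEFAULT_SCALE: clr_per_cell(R),
}


def normalize(
    R: TagCountMatrix, method: str, scale: float = DEFAULT_SCALE
) -> NormalizedTagMatrix:
    """Dispatch to one of the four normalization methods by name."""
    if method not in _DISPATCH:
        raise ValueError(f"unknown normalization method {method!r}; choose from {METHODS}")
    return _DISPATCH[method](R, scale=scale)
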