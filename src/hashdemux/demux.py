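"""Clustering-based sample assignment from hashtag counts.

The workflow assigns every cell one of {tag name, "Doublet", "Negative"}:

1. cluster cells in normalized tag space (SNN graph + Louvain);
2. for each cluster, find *marker tags* by a one-vs-rest two-sided Wilcoxon
   rank-sum test on normalized values; a marker must be expressed (count > 0)
   in every cell of the cluster, have an adjusted p-value < .05, and a log
   fold-change at or above a threshold;
3. label clusters: no marker -> Negative, one marker -> that tag, two or more
   markers -> Doublet;
4. calibrate the logFC threshold over a candidate grid so the resulting
   doublet fraction is closest to the expected doublet rate (ties broken by
   the smallest threshold);
5. repeat over a grid of (k, resolution) clustering parameters and take a
   per-cell majority vote; the fraction of runs agreeing with the winning
   label is reported as a confidence score.

The expected doublet rate may be supplied by the user (e.g. the known rate of
a simulation or a loading-table estimate) or computed for a standard 10x 3'
v3.1 run as ``8e-6 * n_cells * (n_tags - 1) / n_tags``.

The log fold-change for tag *i* in cluster *c* is the natural log of the
ratio of de-normalized means with pseudocount one:
``logFC = ln((mean_{j in c} expm1(n_ij) + 1) / (mean_{j not in c} expm1(n_ij) + 1))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .graph_cluster import ClusterAssignment, ParameterError, build_snn, louvain
from .io_formats import DOUBLET, NEGATIVE, TagCountMatrix
from .normalization import DEFAULT_SCALE, NormalizedTagMatrix, normalize

DEFAULT_K_GRID = (5, 10, 15, 20, 25, 30)
DEFAULT_RESOLUTION_GRID = (1.0, 2.0, 3.0, 4.0)
DEFAULT_LOG_FC_GRID = tuple(round(0.1 * i, 10) for i in range(1, 21))
P_ADJUSTED_CUTOFF = 0.05


def expected_doublet_rate(n_cells: int, n_tags: int) -> float:
    """Expected doublet fraction for a standard 10x Genomics 3' v3.1 assay.

    ``8e-6 * n_cells * (n_tags - 1) / n_tags``: droplet co-encapsulation
    scales linearly with loading, and only pairs from different samples
    (fraction (T-1)/T) are detectable as cross-tag doublets.
    """
    if n_cells < 1 or n_tags < 1:
        raise ParameterError("n_cells and n_tags must be positive")
    return 8e-6 * n_cells * (n_tags - 1) / n_tags


@dataclass
class MarkerRecord:
    """One retained (cluster, tag) marker from the one-vs-rest Wilcoxon scan."""

    cluster_id: int
    tag: str
    log_fc: float
    p_value: float
    p_adjusted: float
    fraction_expressed_in_cluster: float


@dataclass
class RunLabeling:
    """Labels from a single (k, resolution) clustering run."""

    k: int
    resolution: float
    seed: int
    chosen_log_fc: float
    labels: np.ndarray  # per-cell object array of tag | Doublet | Negative
    doublet_rate_achieved: float


@dataclass
class DemuxResult:
    """Ensemble majority-vote result.

    ``confidence[j]`` is the fraction of successful runs whose label for cell
    *j* equals the final (modal) label — always at least ``1 / n_runs``.
    """

    barcodes: list[str]
    final_labels: np.ndarray
    confidence: np.ndarray
    runs: list[RunLabeling] = field(default_factory=list)
    expected_rate: float = 0.0

    def to_label_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.barcodes,
                "label": self.final_labels,
                "confidence": self.confidence,
            }
        )

    def report(self) -> dict:
        """Per-run calibration summary (JSON-serializable)."""
        return {
            "expected_doublet_rate": self.expected_rate,
            "n_runs": len(self.runs),
            "runs": [
                {
                    "k": r.k,
                    "resolution": r.resolution,
                    "seed": r.seed,
                    "chosen_log_fc": r.chosen_log_fc,
                    "doublet_rate_achieved": r.doublet_rate_achieved,
                }
                for r in self.runs
            ],
        }


def _marker_statistics(
    N: NormalizedTagMatrix, clusters: ClusterAssignment, p_adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Wilcoxon statistics for every (cluster, tag) one-vs-rest contrast.

    The log-FC threshold only filters these records, so they are computed once
    per clustering and reused across calibration candidates. Clusters of size
    one are degenerate for the rank-sum test and are skipped with a warning.
    """
    values = N.values
    rows = []
    for c in range(clusters.n_clusters):
        in_c = clusters.cluster_id == c
        size = int(in_c.sum())
        if size < 2 or size == N.n_cells:
            warnings.warn(
                f"cluster {c} has {size} cell(s) (or no complement); "
                "marker test skipped",
                stacklevel=3,
            )
            continue
        for i, tag in enumerate(N.tag_names):
            x = values[i, in_c]
            y = values[i, ~in_c]
            frac = float((x > 0).mean())
            mean_in = np.expm1(x).mean() + 1.0
            mean_out = np.expm1(y).mean() + 1.0
            log_fc = float(np.log(mean_in / mean_out))
            stat_p = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
            rows.append((c, tag, log_fc, float(stat_p), frac))
    df = pd.DataFrame(
        rows, columns=["cluster_id", "tag", "log_fc", "p_value", "fraction_expressed"]
    )
    if df.empty:
        df["p_adjusted"] = pd.Series(dtype=float)
        return df
    n_tests = len(df)
    if p_adjust == "bonferroni":
        df["p_adjusted"] = np.minimum(df["p_value"] * n_tests, 1.0)
    elif p_adjust == "bh":
        order = np.argsort(df["p_value"].to_numpy())
        ranked = df["p_value"].to_numpy()[order] * n_tests / (np.arange(n_tests) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(n_tests)
        out[order] = np.minimum(adj, 1.0)
        df["p_adjusted"] = out
    else:
        raise ValueError(f"unknown adjustment {p_adjust!r}")
    return df


def _filter_markers(stats: pd.DataFrame, log_fc_threshold: float) -> pd.DataFrame:
    return stats[
        (stats["fraction_expressed"] == 1.0)
        & (stats["p_adjusted"] < P_ADJUSTED_CUTOFF)
        & (stats["log_fc"] >= log_fc_threshold)
    ]


def find_markers(
    N: NormalizedTagMatrix,
    clusters: ClusterAssignment,
    log_fc_threshold: float,
    p_adjust: str = "bonferroni",
) -> list[MarkerRecord]:
    """Marker tags per cluster by one-vs-rest Wilcoxon rank-sum.

    A record is retained iff the tag is expressed (normalized value > 0,
    equivalently raw count > 0) in every cell of the cluster, the adjusted
    p-value is below .05, and the logFC is at or above the threshold.
    """
    stats = _marker_statistics(N, clusters, p_adjust=p_adjust)
    kept = _filter_markers(stats, log_fc_threshold)
    return [
        MarkerRecord(
            int(r.cluster_id),
            r.tag,
            float(r.log_fc),
            float(r.p_value),
            float(r.p_adjusted),
            float(r.fraction_expressed),
        )
        for r in kept.itertuples()
    ]


def label_from_markers(
    clusters: ClusterAssignment, markers: list[MarkerRecord] | pd.DataFrame
) -> np.ndarray:
    """Map clusters to labels: 0 markers -> Negative, 1 -> the tag, >=2 -> Doublet."""
    if isinstance(markers, pd.DataFrame):
        pairs = list(zip(markers["cluster_id"], markers["tag"]))
    else:
        pairs = [(m.cluster_id, m.tag) for m in markers]
    per_cluster: dict[int, list[str]] = {}
    for c, tag in pairs:
        per_cluster.setdefault(int(c), []).append(tag)
    cluster_label = {}
    for c in range(clusters.n_clusters):
        tags = per_cluster.get(c, [])
        if len(tags) == 0:
            cluster_label[c] = NEGATIVE
        elif len(tags) == 1:
            cluster_label[c] = tags[0]
        else:
            cluster_label[c] = DOUBLET
    return np.array([cluster_label[c] for c in clusters.cluster_id], dtype=object)


def calibrate_log_fc(
    N: NormalizedTagMatrix,
    clusters: ClusterAssignment,
    target_rate: float,
    candidate_grid=DEFAULT_LOG_FC_GRID,
    p_adjust: str = "bonferroni",
) -> tuple[float, np.ndarray]:
    """Choose the logFC threshold whose doublet fraction is closest to target.

    Evaluates every candidate threshold (the rank-sum statistics are shared —
    only the filter changes), computes the fraction of all cells labeled
    Doublet, and returns the candidate minimizing ``|achieved - target|``;
    exact ties go to the smallest threshold.
    """
    candidates = sorted(candidate_grid)
    if not candidates:
        raise ParameterError("empty logFC candidate grid")
    stats = _marker_statistics(N, clusters, p_adjust=p_adjust)
    best = None
    for thr in candidates:  # ascending, so strict '<' keeps the smallest tie
        labels = label_from_markers(clusters, _filter_markers(stats, thr))
        achieved = float((labels == DOUBLET).mean())
        gap = abs(achieved - target_rate)
        if best is None or gap < best[0]:
            best = (gap, thr, labels)
    _, chosen, labels = best
    return float(chosen), labels


def demux_single(
    N: NormalizedTagMatrix,
    k: int,
    resolution: float,
    seed: int,
    expected_rate: float,
    log_fc_grid=DEFAULT_LOG_FC_GRID,
    prune_threshold: float | None = None,
    p_adjust: str = "bonferroni",
) -> RunLabeling:
    """One clustering-and-labeling pass at fixed (k, resolution)."""
    snn_kwargs = {} if prune_threshold is None else {"prune_threshold": prune_threshold}
    graph = build_snn(N, k, **snn_kwargs)
    clusters = louvain(graph, resolution=resolution, seed=seed)
    chosen, labels = calibrate_log_fc(
        N, clusters, expected_rate, candidate_grid=log_fc_grid, p_adjust=p_adjust
    )
    return RunLabeling(
        k=k,
        resolution=resolution,
        seed=seed,
        chosen_log_fc=chosen,
        labels=labels,
        doublet_rate_achieved=float((labels == DOUBLET).mean()),
    )


def _majority_vote(label_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Modal label per cell with deterministic tie-breaking.

    Ties are resolved conservatively: Negative beats Doublet beats tag names
    (alphabetical among tags), so an ambiguous cell is never forced into a
    sample.
    """
    n_runs, n_cells = label_matrix.shape

    def priority(label: str) -> tuple:
        if label == NEGATIVE:
            return (0,)
        if label == DOUBLET:
            return (1,)
        return (2, label)

    final = np.empty(n_cells, dtype=object)
    confidence = np.empty(n_cells, dtype=float)
    for j in range(n_cells):
        values, counts = np.unique(label_matrix[:, j].astype(str), return_counts=True)
        top = counts.max()
        tied = [v for v, c in zip(values, counts) if c == top]
        winner = min(tied, key=priority)
        final[j] = winner
        confidence[j] = top / n_runs
    return final, confidence


def demux_ensemble(
    R: TagCountMatrix,
    method: str = "clr_seq_depth",
    k_grid=DEFAULT_K_GRID,
    resolution_grid=DEFAULT_RESOLUTION_GRID,
    expected_rate: float | str = "auto",
    scale: float = DEFAULT_SCALE,
    base_seed: int = 0,
    log_fc_grid=DEFAULT_LOG_FC_GRID,
    p_adjust: str = "bonferroni",
) -> DemuxResult:
    """Demultiplex by majority vote over the (k, resolution) ensemble.

    Runs ``demux_single`` for every combination in ``k_grid`` x
    ``resolution_grid`` (per-run seed = base_seed + run index) and takes the
    per-cell modal label. A failing run is dropped with a warning (shrinking
    the confidence denominator); if every run fails an error is raised.
    """
    if not k_grid or not resolution_grid:
        raise ParameterError("k_grid and resolution_grid must be nonempty")
    if expected_rate == "auto":
        rate = expected_doublet_rate(R.n_cells, R.n_tags)
    else:
        rate = float(expected_rate)
    N = normalize(R, method, scale=scale)
    runs: list[RunLabeling] = []
    run_index = 0
    for k in k_grid:
        for res in resolution_grid:
            seed = base_seed + run_index
            run_index += 1
            try:
                runs.append(
                    demux_single(
                        N, k, res, seed, rate,
                        log_fc_grid=log_fc_grid, p_adjust=p_adjust,
                    )
                )
            except Exception as exc:  # drop the run, keep the ensemble
                warnings.warn(
                    f"run (k={k}, resolution={res}) failed and was dropped: {exc}",
                    stacklevel=2,
                )
    if not runs:
        raise RuntimeError("all ensemble runs failed")
    label_matrix = np.vstack([r.labels for r in runs])
    final, confidence = _majority_vote(label_matrix)
    return DemuxResult(
        barcodes=list(R.barcodes),
        final_labels=final,
        confidence=confidence,
        runs=runs,
        expected_rate=rate,
    )
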