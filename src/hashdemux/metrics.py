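"""Evaluation statistics for demultiplexing results and datasets.

Classification quality is summarized by per-tag F-scores (macro-averaged over
the true tag classes; Doublet and Negative are not averaged classes but wrong
calls against them count as errors) and by the fraction of true doublets
misclassified as singlets.

Per-tag *separability* — how well a tag's count distribution distinguishes
cells carrying the tag from all other cells — is the area under the
precision-recall curve (AUCPR). Ground-truth doublets are excluded first;
positives are the cells truly labeled with the tag. Each distinct score value
defines a threshold (cells *above* it are called positive); the area uses the
nonlinear precision-recall interpolation of Davis & Goadrich between
operating points, with the segment from recall 0 to the first attainable
positive-recall point taken at that point's precision. AUCPR is invariant
under strictly monotone per-tag transforms of the scores.

Two dataset-level noise statistics quantify background contamination:

* ``baseline_expression_variability`` — coefficient of variation across tags
  of the per-tag median of log(count + 1); elevated when some tags have a
  high ambient baseline in all cells.
* ``sequencing_depth_variability`` — ratio of the 99th to the 1st percentile
  of per-cell total tag counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import DOUBLET, NEGATIVE, TagCountMatrix, ValidationError, as_label_table
from .normalization import NormalizedTagMatrix


def _aligned_labels(pred, truth) -> tuple[pd.Series, pd.Series]:
    p = as_label_table(pred).set_index("barcode")["label"]
    t = as_label_table(truth).set_index("barcode")["label"]
    if set(p.index) != set(t.index):
        raise ValidationError("prediction and truth barcodes differ")
    return p.reindex(t.index), t


def f_score(pred, truth) -> tuple[dict[str, float], float]:
    """Per-tag F1 and the macro average over tags present in the truth.

    For tag t: precision and recall of the binary call (pred == t) against
    (truth == t); F = 2PR/(P+R), defined as 0 when P + R = 0. Doublet and
    Negative predictions on true-tag cells count as missed recalls; tag
    predictions on true doublets/negatives count against precision.
    """
    p, t = _aligned_labels(pred, truth)
    tags = sorted(set(t) - {DOUBLET, NEGATIVE})
    per_tag = {}
    for tag in tags:
        tp = int(((p == tag) & (t == tag)).sum())
        fp = int(((p == tag) & (t != tag)).sum())
        fn = int(((p != tag) & (t == tag)).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        per_tag[tag] = (
            2 * precision * recall / (precision + recall) if precision + recall else 0.0
        )
    average = float(np.mean(list(per_tag.values()))) if per_tag else float("nan")
    return per_tag, average


def doublet_misclassification(pred, truth) -> float:
    """Fraction of true doublets assigned to a single sample (a tag name).

    Doublets predicted Doublet or Negative are not counted as misclassified
    into a singlet. Returns 0 (with a warning) when the truth has no doublets.
    """
    p, t = _aligned_labels(pred, truth)
    doublets = t == DOUBLET
    n_doublets = int(doublets.sum())
    if n_doublets == 0:
        warnings.warn("truth contains no doublets; misclassification set to 0")
        return 0.0
    as_singlet = doublets & ~p.isin([DOUBLET, NEGATIVE])
    return float(as_singlet.sum() / n_doublets)


def _pr_points(scores: np.ndarray, positive: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (TP, FP) at every distinct threshold, best score first.

    All cells tied at one score value enter together, so the operating points
    are stable under tie-preserving monotone transforms.
    """
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    pos = positive[order].astype(np.int64)
    # last index of each tie group
    boundaries = np.nonzero(np.diff(s))[0]
    ends = np.append(boundaries, len(s) - 1)
    tp = np.cumsum(pos)[ends]
    fp = (ends + 1) - tp
    return tp, fp


def _aucpr_from_points(tp: np.ndarray, fp: np.ndarray, n_pos: int) -> float:
    """Area from operating points: initial rectangle + Davis-Goadrich segments.

    Between consecutive points (TP1, FP1) -> (TP2, FP2) the interpolated
    precision at TP1 + x is (TP1+x) / (TP1+x + FP1 + s*x) with
    s = (FP2-FP1)/(TP2-TP1); its integral over x in [0, ΔTP], divided by the
    number of positives, is the recall-axis area of the segment.
    """
    area = 0.0
    prev = None
    for tp_k, fp_k in zip(tp, fp):
        if tp_k == 0:
            prev = (tp_k, fp_k)
            continue
        if prev is None or prev[0] == 0:
            # rectangle from recall 0 to the first attainable point
            area += (tp_k / n_pos) * (tp_k / (tp_k + fp_k))
        else:
            a, b = prev
            delta = tp_k - a
            if delta > 0:
                s = (fp_k - b) / delta
                c = a + b
                d = 1.0 + s
                integral = delta / d + (a - c / d) / d * np.log((c + d * delta) / c)
                area += integral / n_pos
            # delta == 0: recall unchanged, no area
        prev = (tp_k, fp_k)
    return float(min(max(area, 0.0), 1.0))  # guard float drift at the ends


def aucpr_separability(
    X: TagCountMatrix | NormalizedTagMatrix, truth, tag: str
) -> float | None:
    """AUCPR of one tag's counts separating its cells from all others.

    Ground-truth doublets are excluded; positives are cells whose true label
    equals ``tag``. Returns None (missing) when no positive or no negative
    cells remain after exclusion.
    """
    t = as_label_table(truth).set_index("barcode")["label"]
    barcodes = X.barcodes
    if set(t.index) != set(barcodes):
        raise ValidationError("truth barcodes do not match the matrix")
    t = t.reindex(barcodes)
    if tag not in X.tag_names:
        raise ValidationError(f"unknown tag {tag!r}")
    values = X.counts if isinstance(X, TagCountMatrix) else X.values
    scores = np.asarray(values[X.tag_names.index(tag)], dtype=float)
    keep = (t != DOUBLET).to_numpy()
    scores = scores[keep]
    positive = (t[keep] == tag).to_numpy()
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn(f"tag {tag!r} has no positives or no negatives; AUCPR undefined")
        return None
    tp, fp = _pr_points(scores, positive)
    return _aucpr_from_points(tp, fp, n_pos)


def baseline_expression_variability(R: TagCountMatrix) -> float:
    """CV across tags of the per-tag median of ln(count + 1).

    Sample standard deviation (n - 1). Returns NaN with a warning when the
    mean of medians is zero (e.g. an all-zero matrix).
    """
    medians = np.median(np.log1p(R.counts.astype(float)), axis=1)
    mean = medians.mean()
    if mean == 0:
        warnings.warn("mean of per-tag medians is zero; statistic undefined")
        return float("nan")
    return float(np.std(medians, ddof=1) / mean)


def sequencing_depth_variability(R: TagCountMatrix) -> float:
    """Ratio of the 99th to the 1st percentile of per-cell total tag counts.

    Linear-interpolation percentiles. Infinite (with a warning) when the 1st
    percentile is zero.
    """
    totals = R.counts.sum(axis=0).astype(float)
    p1 = np.percentile(totals, 1)
    p99 = np.percentile(totals, 99)
    if p1 == 0:
        warnings.warn("1st percentile of totals is zero; depth variability infinite")
        return float("inf")
    return float(p99 / p1)


@dataclass
class EvaluationReport:
    """All evaluation statistics for one prediction/dataset pair.

    ``per_tag_aucpr`` values may be None (missing) for tags with no positives
    after doublet exclusion — missing is distinct from zero.
    """

    per_tag_f: dict[str, float]
    average_f: float
    doublet_to_singlet_rate: float
    per_tag_aucpr: dict[str, float | None]
    baseline_expression_variability: float
    sequencing_depth_variability: float

    def to_dict(self) -> dict:
        def enc(x):
            if x is None:
                return None
            if isinstance(x, float) and np.isnan(x):
                return None
            if isinstance(x, float) and np.isinf(x):
                return "inf"
            return float(x)

        return {
            "per_tag_f": {k: enc(v) for k, v in self.per_tag_f.items()},
            "average_f": enc(self.average_f),
            "doublet_to_singlet_rate": enc(self.doublet_to_singlet_rate),
            "per_tag_aucpr": {k: enc(v) for k, v in self.per_tag_aucpr.items()},
            "baseline_expression_variability": enc(self.baseline_expression_variability),
            "sequencing_depth_variability": enc(self.sequencing_depth_variability),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        def dec(x):
            if x == "inf":
                return float("inf")
            return x

        return cls(
            per_tag_f=dict(d["per_tag_f"]),
            average_f=d["average_f"],
            doublet_to_singlet_rate=d["doublet_to_singlet_rate"],
            per_tag_aucpr=dict(d["per_tag_aucpr"]),
            baseline_expression_variability=dec(d["baseline_expression_variability"]),
            sequencing_depth_variability=dec(d["sequencing_depth_variability"]),
        )


def evaluate(pred, truth, R: TagCountMatrix) -> EvaluationReport:
    """Assemble the full evaluation report for predictions against truth."""
    per_tag_f, average = f_score(pred, truth)
    aucpr = {tag: aucpr_separability(R, truth, tag) for tag in R.tag_names}
    return EvaluationReport(
        per_tag_f=per_tag_f,
        average_f=average,
        doublet_to_singlet_rate=doublet_misclassification(pred, truth),
        per_tag_aucpr=aucpr,
        baseline_expression_variability=baseline_expression_variability(R),
        sequencing_depth_variability=sequencing_depth_variability(R),
    )
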