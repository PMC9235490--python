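"""Ranking metrics and branch-level diagnostics.

Classification of binding sites is heavily imbalanced, so methods are
compared by the area under the precision-recall curve and by the recall
achievable while keeping the empirical false discovery rate (1 -
precision at a cutoff) below a threshold.  Branch informativeness asks
which tree edges actually separate the classes: the mean per-edge
log-likelihood-ratio term of positive examples minus that of negatives.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve

from .model import PhyloPGMModel, edge_llr_terms
from .score_table import OrthologScoreTable

__all__ = [
    "UndefinedMetricError",
    "BranchContribution",
    "EvaluationReport",
    "aupr",
    "recall_at_fdr",
    "pr_curve_points",
    "branch_informativeness",
    "evaluation_report",
]

DEFAULT_FDR_GRID = (0.01, 0.05, 0.10, 0.25, 0.50)


class UndefinedMetricError(ValueError):
    """Raised when a ranking metric is requested for single-class labels."""


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    if labels.min() == labels.max():
        raise UndefinedMetricError(
            "metric undefined: need at least one positive and one negative"
        )
    return labels


def aupr(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve (step-wise, ties grouped).

    This is the standard average-precision estimator: ranking by score
    descending, tied scores entering as a block, with the step-wise
    (non-interpolated) precision rule.
    """
    labels = _check_two_classes(np.asarray(labels))
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def recall_at_fdr(
    scores: Sequence[float], labels: Sequence[int], fdr_threshold: float
) -> float:
    """Recall at the most permissive cutoff with empirical FDR <= threshold.

    FDR at a cutoff is 1 - precision among examples scoring at or above
    it.  Returns 0.0 when no cutoff qualifies.
    """
    if not 0.0 < fdr_threshold < 1.0:
        raise ValueError(f"fdr_threshold must be in (0, 1), got {fdr_threshold}")
    labels = _check_two_classes(np.asarray(labels))
    precision, recall, thresholds = precision_recall_curve(
        labels, np.asarray(scores, dtype=float)
    )
    # drop the synthetic final (precision=1, recall=0) endpoint: it does
    # not correspond to any attainable cutoff
    precision, recall = precision[: len(thresholds)], recall[: len(thresholds)]
    ok = (1.0 - precision) <= fdr_threshold
    return float(recall[ok].max()) if ok.any() else 0.0


def pr_curve_points(scores: Sequence[float], labels: Sequence[int]) -> Dict[str, list]:
    """Precision-recall curve points (for CSV export / plotting elsewhere)."""
    labels = _check_two_classes(np.asarray(labels))
    precision, recall, thresholds = precision_recall_curve(
        labels, np.asarray(scores, dtype=float)
    )
    return {
        "threshold": [float(t) for t in thresholds],
        "precision": [float(p) for p in precision[: len(thresholds)]],
        "recall": [float(r) for r in recall[: len(thresholds)]],
    }


@dataclass(frozen=True)
class BranchContribution:
    parent: str
    child: str
    mean_llr_positive: float
    mean_llr_negative: float
    informativeness: float
    n_positive: int
    n_negative: int


def branch_informativeness(
    model: PhyloPGMModel, table: OrthologScoreTable
) -> List[BranchContribution]:
    """Per-edge separation of classes by the edge's LLR term.

    For each edge, the per-example log-likelihood-ratio term (unweighted
    by alpha) is averaged separately over positive and negative
    examples, counting only examples where the edge actually contributed
    (neither endpoint missing); the difference of means is the edge's
    informativeness.  Edges are returned sorted by informativeness,
    descending.  An edge that never contributes is reported as 0 with
    zero counts.
    """
    if table.labels is None:
        raise ValueError("table must carry labels")
    y = _check_two_classes(table.labels.to_numpy())
    edges, terms, contributed = edge_llr_terms(model, table)
    out = []
    for j, (parent, child) in enumerate(edges):
        pos = contributed[:, j] & (y == 1)
        neg = contributed[:, j] & (y == 0)
        mean_pos = float(terms[pos, j].mean()) if pos.any() else 0.0
        mean_neg = float(terms[neg, j].mean()) if neg.any() else 0.0
        info = mean_pos - mean_neg if (pos.any() or neg.any()) else 0.0
        out.append(
            BranchContribution(
                parent=parent,
                child=child,
                mean_llr_positive=mean_pos,
                mean_llr_negative=mean_neg,
                informativeness=info,
                n_positive=int(pos.sum()),
                n_negative=int(neg.sum()),
            )
        )
    out.sort(key=lambda b: b.informativeness, reverse=True)
    return out


@dataclass
class EvaluationReport:
    """AUPR and recall-at-FDR per method, over one labeled test set."""

    n_positives: int
    n_negatives: int
    methods: Dict[str, Dict] = field(default_factory=dict)

    def to_json(self, indent: Optional[int] = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True)


def evaluation_report(
    scores_by_method: Mapping[str, Sequence[float]],
    labels: Sequence[int],
    fdr_grid: Sequence[float] = DEFAULT_FDR_GRID,
) -> EvaluationReport:
    """Tabulate AUPR and recall at each FDR threshold for several methods."""
    y = _check_two_classes(np.asarray(labels))
    report = EvaluationReport(
        n_positives=int((y == 1).sum()), n_negatives=int((y == 0).sum())
    )
    for method, scores in scores_by_method.items():
        report.methods[method] = {
            "aupr": aupr(scores, y),
            "recall_at_fdr": {
                f"{f:g}": recall_at_fdr(scores, y, f) for f in fdr_grid
            },
        }
    return report
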