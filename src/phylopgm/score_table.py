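"""Per-example ortholog score tables and their 12-bin discretization.

A score table holds one row per genomic example and one column per
species/ancestor: each entry is the base predictor's score on that
species' orthologous sequence, in [0, 1], or missing when no ortholog
exists.  Scores are discretized by rounding to the first decimal place
into bins 0..10, with bin 11 reserved for missing values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from numbers import Real
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .tree import PhyloTree

__all__ = [
    "MISSING_BIN",
    "N_BINS",
    "ScoreTableError",
    "OrthologScoreTable",
    "discretize",
    "discretize_array",
    "read_score_table",
]

#: number of discretization bins: 0.0, 0.1, ..., 1.0 plus a missing-value bin
N_BINS = 12
#: index of the bin reserved for missing scores
MISSING_BIN = 11

_NA_VALUES = ("", "NA", "nan", "NaN")


class ScoreTableError(ValueError):
    """Raised for malformed or tree-inconsistent score tables."""


def discretize(score) -> int:
    """Map a score in [0, 1] (or missing) to a bin index in 0..11.

    ``None`` and NaN map to the missing bin (11).  Scores are rounded to
    the first decimal place with ties rounded half away from zero
    (0.25 -> bin 3); out-of-range values are clipped to [0, 1] with a
    warning, since sigmoid-output predictors can only violate the range
    by float artifacts.
    """
    if score is None:
        return MISSING_BIN
    if isinstance(score, bool) or not isinstance(score, Real):
        raise TypeError(f"score must be a real number or missing, got {score!r}")
    x = float(score)
    if math.isnan(x):
        return MISSING_BIN
    if x < 0.0 or x > 1.0:
        warnings.warn(f"score {x} outside [0, 1]; clipping", stacklevel=2)
        x = min(max(x, 0.0), 1.0)
    return int(math.floor(x * 10.0 + 0.5))


def discretize_array(values: np.ndarray) -> np.ndarray:
    """Vectorized :func:`discretize` over a float array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    bins = np.full(values.shape, MISSING_BIN, dtype=np.int64)
    present = ~np.isnan(values)
    if np.any((values[present] < 0.0) | (values[present] > 1.0)):
        warnings.warn("scores outside [0, 1] present; clipping", stacklevel=2)
    clipped = np.clip(values[present], 0.0, 1.0)
    bins[present] = np.floor(clipped * 10.0 + 0.5).astype(np.int64)
    return bins


@dataclass
class OrthologScoreTable:
    """Scores of a base predictor on each example's orthologs.

    Attributes
    ----------
    scores:
        float DataFrame, index = example ids, columns = species/node
        names, NaN = missing ortholog.
    labels:
        optional int Series aligned to the index with values in {0, 1}
        (1 = binding site).
    """

    scores: pd.DataFrame
    labels: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            dups = self.scores.index[self.scores.index.duplicated()].tolist()
            raise ScoreTableError(f"duplicate example ids: {dups[:5]}")
        vals = self.scores.to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if np.any((vals[present] < 0.0) | (vals[present] > 1.0)):
            warnings.warn("scores outside [0, 1]; clipping to range", stacklevel=2)
            self.scores = self.scores.clip(lower=0.0, upper=1.0)
        if self.labels is not None:
            self.labels = self.labels.reindex(self.scores.index)
            bad = ~self.labels.isin([0, 1])
            if bad.any():
                raise ScoreTableError(
                    f"labels must be 0 or 1; offending ids: "
                    f"{self.labels.index[bad].tolist()[:5]}"
                )
            self.labels = self.labels.astype(np.int64)

    # -- basic accessors ----------------------------------------------------

    @property
    def example_ids(self) -> List[str]:
        return list(self.scores.index)

    @property
    def species(self) -> List[str]:
        return list(self.scores.columns)

    @property
    def n_examples(self) -> int:
        return len(self.scores)

    def subset(self, ids: Sequence[str]) -> "OrthologScoreTable":
        labels = self.labels.loc[list(ids)] if self.labels is not None else None
        return OrthologScoreTable(self.scores.loc[list(ids)].copy(), labels)

    def bins_for(self, nodes: Sequence[str]) -> np.ndarray:
        """(n_examples, len(nodes)) int array of bins; absent columns = missing."""
        sub = self.scores.reindex(columns=list(nodes))
        return discretize_array(sub.to_numpy(dtype=float))

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        if self.labels is not None:
            out["label"] = self.labels
        out.to_csv(
            path, sep="\t", na_rep="NA", index_label="example_id", float_format="%.6f"
        )

    @classmethod
    def from_frame(
        cls, scores: pd.DataFrame, labels: Optional[pd.Series] = None
    ) -> "OrthologScoreTable":
        return cls(scores.astype(float), labels)


def read_score_table(
    path,
    tree: Optional[PhyloTree] = None,
    *,
    strict: bool = True,
    focal: Optional[str] = None,
) -> OrthologScoreTable:
    """Read a TSV score table and (optionally) align it to a tree.

    The file must have an ``example_id`` header column, one column per
    species, and an optional trailing ``label`` column; empty cells or
    ``NA`` denote missing scores.  Species columns absent from ``tree``
    raise (strict) or are dropped with a warning (lenient); tree nodes
    absent from the table are simply treated as all-missing downstream.
    """
    raw = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        na_values=list(_NA_VALUES),
        keep_default_na=False,
    )
    if raw.index.name != "example_id":
        raise ScoreTableError(
            f"first column must be named 'example_id', got {raw.index.name!r}"
        )
    labels = None
    if "label" in raw.columns:
        lab_raw = raw.pop("label")
        labels = pd.to_numeric(lab_raw, errors="coerce")
        if labels.isna().any():
            bad = labels.index[labels.isna()][0]
            raise ScoreTableError(f"unparseable label in row {bad!r}")

    cols = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad][0]
            raise ScoreTableError(
                f"unparseable numeric cell at row {row!r}, column {col!r}: "
                f"{raw.loc[row, col]!r}"
            )
        cols[col] = converted
    scores = pd.DataFrame(cols, index=raw.index)

    if tree is not None:
        known = tree.nodes
        unknown = [c for c in scores.columns if c not in known]
        if unknown:
            if strict:
                raise ScoreTableError(
                    f"species columns not present in the tree: {unknown}"
                )
            warnings.warn(
                f"dropping {len(unknown)} column(s) not in the tree: {unknown}",
                stacklevel=2,
            )
            scores = scores.drop(columns=unknown)
    if focal is not None and focal not in scores.columns:
        raise ScoreTableError(f"focal species column {focal!r} absent from table")
    return OrthologScoreTable(scores, labels)
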