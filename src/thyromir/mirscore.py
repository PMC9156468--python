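"""The miR-score: average log2 expression of the selected marker miRNAs.

The markers are down-regulated in malignancy, so a *low* score predicts a
malignant nodule; a sample scoring exactly at the cutoff is called
malignant, favouring sensitivity (the score is a rule-out test).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import NormalizedMatrix


class ScoreError(ValueError):
    pass


@dataclass
class MiRScoreModel:
    """Marker set, orientation and fitted decision cutoff."""

    marker_ids: tuple[str, ...]
    orientation: str = "low_means_malignant"
    cutoff: float | None = None
    training: str = ""

    def __post_init__(self) -> None:
        self.marker_ids = tuple(self.marker_ids)
        if len(self.marker_ids) < 1:
            raise ScoreError("a score model needs at least one marker")
        if self.orientation not in ("low_means_malignant", "high_means_malignant"):
            raise ScoreError(f"unknown orientation {self.orientation!r}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "marker_ids": list(self.marker_ids),
                "orientation": self.orientation,
                "cutoff": self.cutoff,
                "training": self.training,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MiRScoreModel":
        d = json.loads(text)
        return cls(
            marker_ids=tuple(d["marker_ids"]),
            orientation=d.get("orientation", "low_means_malignant"),
            cutoff=d.get("cutoff"),
            training=d.get("training", ""),
        )


def compute_score(norm: NormalizedMatrix, marker_ids) -> pd.Series:
    """Per-sample arithmetic mean of marker log2 expression."""
    if norm.log2_expr is None:
        raise ScoreError("normalized matrix has no log2 expression")
    markers = list(marker_ids)
    missing = [m for m in markers if m not in norm.log2_expr.index]
    if missing:
        raise ScoreError(f"marker(s) absent from matrix: {missing}")
    return norm.log2_expr.loc[markers].mean(axis=0).rename("mir_score")


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided P (t on n−2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ScoreError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ScoreError("correlation needs at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ScoreError("constant vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def marker_correlations(
    norm: NormalizedMatrix, marker_ids, sample_ids=None
) -> pd.DataFrame:
    """Pairwise marker correlations (r, P) over the given samples.

    For the two-marker default this is a single row; with more markers every
    unordered pair is reported.
    """
    if norm.log2_expr is None:
        raise ScoreError("normalized matrix has no log2 expression")
    markers = list(marker_ids)
    expr = norm.log2_expr if sample_ids is None else norm.log2_expr.loc[:, list(sample_ids)]
    rows = []
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            r, p = pearson_correlation(expr.loc[markers[i]], expr.loc[markers[j]])
            rows.append({"marker_a": markers[i], "marker_b": markers[j], "r": r, "p": p})
    return pd.DataFrame(rows)


def apply_cutoff(scores: pd.Series, model: MiRScoreModel) -> pd.Series:
    """Classify samples: malignant iff the score falls on the malignant side
    of the cutoff (score <= cutoff for the default low-means-malignant
    orientation; the boundary is always called malignant)."""
    if model.cutoff is None:
        raise ScoreError("model has no fitted cutoff")
    s = np.asarray(scores, dtype=float)
    if model.orientation == "low_means_malignant":
        malignant = s <= model.cutoff
    else:
        malignant = s >= model.cutoff
    return pd.Series(
        np.where(malignant, "malignant", "benign"), index=scores.index, name="predicted"
    )
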