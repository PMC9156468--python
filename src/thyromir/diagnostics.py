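"""Diagnostic performance: ROC/AUC, Youden cutoff, bootstrap CIs, contingency metrics.

Truth labels come from histology: follicular adenomas are benign; FV-PTCs
and NIFTPs are malignant (NIFTPs required surgical excision and are counted
as malignant throughout).

The empirical ROC is evaluated on the midpoints between consecutive
distinct scores plus ±∞, so every achievable operating point appears
exactly once and cutoffs are never ambiguous at tied scores.  The AUC is
the trapezoidal area, identical to the Mann-Whitney concordance statistic
with the half-credit tie correction.  Scores are oriented internally so
that "malignant" is predicted at or below a threshold
(``low_means_malignant``, the miR-score convention); passing
``high_means_malignant`` negates the scores first, and reported thresholds
then refer to the oriented scale.

Confidence intervals are percentile intervals from stratified bootstrap
resampling (within-class resampling, 2000 replicates by default).  By
default the Youden cutoff is re-estimated inside every replicate so that
threshold uncertainty propagates into the sensitivity/specificity/
predictive-value intervals; a fixed-cutoff mode is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mirscore import MiRScoreModel, compute_score
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

BENIGN_HISTOLOGIES = frozenset({"FA"})
MALIGNANT_HISTOLOGIES = frozenset({"FV-PTC", "NIFTP"})

METRIC_NAMES = ("auc", "sensitivity", "specificity", "ppv", "npv", "accuracy")


class DiagnosticsError(ValueError):
    pass


def label_malignancy(annotations: pd.DataFrame) -> pd.Series:
    """Map histology to the benign/malignant truth label (NIFTP → malignant)."""
    hist = annotations.set_index("sample_id")["histology"]
    unknown = set(hist) - BENIGN_HISTOLOGIES - MALIGNANT_HISTOLOGIES
    if unknown:
        raise DiagnosticsError(f"unknown histology value(s): {sorted(unknown)}")
    return pd.Series(
        np.where(hist.isin(list(MALIGNANT_HISTOLOGIES)), "malignant", "benign"),
        index=hist.index,
        name="label",
    )


def _orient(scores: np.ndarray, orientation: str) -> np.ndarray:
    if orientation == "low_means_malignant":
        return scores
    if orientation == "high_means_malignant":
        return -scores
    raise DiagnosticsError(f"unknown orientation {orientation!r}")


def _as_bool_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    return arr == "malignant"


def _threshold_grid(values: np.ndarray) -> np.ndarray:
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _roc_points(mal_sorted: np.ndarray, ben_sorted: np.ndarray):
    """Thresholds, sensitivity and specificity over the midpoint grid."""
    thresholds = _threshold_grid(np.concatenate([mal_sorted, ben_sorted]))
    sens = np.searchsorted(mal_sorted, thresholds, side="right") / mal_sorted.size
    spec = 1.0 - np.searchsorted(ben_sorted, thresholds, side="right") / ben_sorted.size
    return thresholds, sens, spec


def _auc(mal_sorted: np.ndarray, ben_sorted: np.ndarray) -> float:
    """P(score_mal < score_ben) + ½·P(equal), via searchsorted counts."""
    n1, n0 = mal_sorted.size, ben_sorted.size
    lo = np.searchsorted(ben_sorted, mal_sorted, side="left")
    hi = np.searchsorted(ben_sorted, mal_sorted, side="right")
    greater = n0 - hi  # benign scores strictly above each malignant score
    ties = hi - lo
    return float((greater.sum() + 0.5 * ties.sum()) / (n1 * n0))


def _best_youden(thresholds, sens, spec) -> tuple[float, float]:
    """Max-J threshold; ties broken by higher sensitivity, then lower threshold."""
    j = sens + spec - 1.0
    jmax = j.max()
    cand = np.flatnonzero(j >= jmax - 1e-12)
    best_sens = sens[cand].max()
    cand = cand[sens[cand] >= best_sens - 1e-12]
    pick = cand[np.argmin(thresholds[cand])]
    return float(thresholds[pick]), float(j[pick])


@dataclass
class ROCCurve:
    """Empirical ROC with its Youden operating point (oriented-score scale)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float
    orientation: str = "low_means_malignant"


def roc_curve(scores, labels, orientation: str = "low_means_malignant") -> ROCCurve:
    """Empirical ROC of a continuous score against benign/malignant labels."""
    s = _orient(np.asarray(scores, dtype=float), orientation)
    y = _as_bool_labels(labels)
    if s.shape != y.shape:
        raise DiagnosticsError("scores and labels differ in length")
    if not np.all(np.isfinite(s)):
        raise DiagnosticsError("scores must be finite")
    if y.all() or (~y).all():
        raise DiagnosticsError("both classes must be present for ROC analysis")
    mal = np.sort(s[y])
    ben = np.sort(s[~y])
    thresholds, sens, spec = _roc_points(mal, ben)
    cutoff, j = _best_youden(thresholds, sens, spec)
    return ROCCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=_auc(mal, ben),
        youden_cutoff=cutoff,
        youden_j=j,
        orientation=orientation,
    )


def youden_cutoff(curve: ROCCurve) -> tuple[float, float]:
    """The curve's max-J operating point as (cutoff, J)."""
    return curve.youden_cutoff, curve.youden_j


@dataclass
class ContingencyTable2x2:
    """Classifier-vs-truth counts: rows predicted, columns true."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DiagnosticsError("contingency counts must be nonnegative")
        if self.total == 0:
            raise DiagnosticsError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _ratio(num: int, denom: int) -> float:
    return num / denom if denom > 0 else math.nan


def performance_from_contingency(table: ContingencyTable2x2) -> dict[str, float]:
    """Point metrics of a binary classifier from its 2×2 table.

    A zero denominator yields NaN ("undefined"), never 0.  For a binary
    marker the AUC is (sensitivity + specificity) / 2 — the area under its
    single-operating-point ROC.
    """
    sens = _ratio(table.tp, table.tp + table.fn)
    spec = _ratio(table.tn, table.tn + table.fp)
    return {
        "auc": (sens + spec) / 2.0,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": _ratio(table.tp, table.tp + table.fp),
        "npv": _ratio(table.tn, table.tn + table.fn),
        "accuracy": _ratio(table.tp + table.tn, table.total),
    }


def contingency_at_cutoff(
    scores, labels, cutoff: float, orientation: str = "low_means_malignant"
) -> ContingencyTable2x2:
    """2×2 table for the rule "malignant iff oriented score <= cutoff"."""
    s = _orient(np.asarray(scores, dtype=float), orientation)
    y = _as_bool_labels(labels)
    pred = s <= cutoff
    return ContingencyTable2x2(
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        fn=int((~pred & y).sum()),
        tn=int((~pred & ~y).sum()),
    )


def mutation_contingency(annotations: pd.DataFrame) -> ContingencyTable2x2:
    """Treat mutation positivity as a malignancy call against histology truth."""
    labels = label_malignancy(annotations)
    mutated = (
        annotations.set_index("sample_id")["mutation_status"].loc[labels.index]
        == "mutated"
    )
    y = labels == "malignant"
    return ContingencyTable2x2(
        tp=int((mutated & y).sum()),
        fp=int((mutated & ~y).sum()),
        fn=int((~mutated & y).sum()),
        tn=int((~mutated & ~y).sum()),
    )


def _replicate_metrics(mal, ben, cutoff):
    """All six metrics of one (possibly resampled) score set at a cutoff."""
    mal = np.sort(mal)
    ben = np.sort(ben)
    if cutoff is None:
        cutoff, _ = _best_youden(*_roc_points(mal, ben))
    n1, n0 = mal.size, ben.size
    tp = int(np.searchsorted(mal, cutoff, side="right"))
    fp = int(np.searchsorted(ben, cutoff, side="right"))
    fn, tn = n1 - tp, n0 - fp
    return {
        "auc": _auc(mal, ben),
        "sensitivity": _ratio(tp, n1),
        "specificity": _ratio(tn, n0),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "accuracy": _ratio(tp + tn, n1 + n0),
    }


def bootstrap_ci(
    scores,
    labels,
    n_reps: int = 2000,
    seed: int = 0,
    orientation: str = "low_means_malignant",
    refit_cutoff: bool = True,
    cutoff: float | None = None,
    metrics: tuple[str, ...] = METRIC_NAMES,
    alpha: float = 0.05,
) -> dict[str, tuple[float, float]]:
    """Stratified-bootstrap percentile CIs for the requested metrics.

    Malignant and benign samples are resampled within class, so every
    replicate retains both classes.  With ``refit_cutoff`` (default) the
    Youden threshold is re-estimated per replicate; otherwise ``cutoff``
    (oriented scale) is held fixed.  Replicates where a metric is undefined
    (empty predicted class) are ignored for that metric's percentiles.
    Deterministic for a fixed seed.
    """
    s = _orient(np.asarray(scores, dtype=float), orientation)
    y = _as_bool_labels(labels)
    if y.all() or (~y).all():
        raise DiagnosticsError("both classes must be present to bootstrap")
    if not refit_cutoff and cutoff is None:
        raise DiagnosticsError("fixed-cutoff bootstrap needs an explicit cutoff")
    unknown = set(metrics) - set(METRIC_NAMES)
    if unknown:
        raise DiagnosticsError(f"unknown metric(s): {sorted(unknown)}")
    mal = s[y]
    ben = s[~y]
    n1, n0 = mal.size, ben.size
    rng = np.random.default_rng(seed)
    idx_m = rng.integers(0, n1, size=(n_reps, n1))
    idx_b = rng.integers(0, n0, size=(n_reps, n0))

    if tuple(metrics) == ("auc",):
        # vectorized AUC-only path (used for large simulation studies)
        aucs = np.empty(n_reps)
        chunk = max(1, int(2_000_000 // max(1, n1 * n0)))
        for start in range(0, n_reps, chunk):
            stop = min(start + chunk, n_reps)
            wm = mal[idx_m[start:stop]][:, :, None]
            wb = ben[idx_b[start:stop]][:, None, :]
            less = (wm < wb).sum(axis=(1, 2))
            ties = (wm == wb).sum(axis=(1, 2))
            aucs[start:stop] = (less + 0.5 * ties) / (n1 * n0)
        lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return {"auc": (float(lo), float(hi))}

    fixed = None if refit_cutoff else cutoff
    collected = {m: np.empty(n_reps) for m in metrics}
    for r in range(n_reps):
        rep = _replicate_metrics(mal[idx_m[r]], ben[idx_b[r]], fixed)
        for m in metrics:
            collected[m][r] = rep[m]
    out = {}
    for m in metrics:
        vals = collected[m]
        vals = vals[np.isfinite(vals)]
        lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        out[m] = (float(lo), float(hi))
    return out


@dataclass
class DiagnosticPerformance:
    """Point estimates with bootstrap CIs, plus cohort context."""

    metrics: dict[str, tuple[float, float, float]]  # name -> (est, lo, hi)
    n_samples: int
    prevalence: float
    cutoff: float | None = None
    n_bootstrap: int = 0
    subset: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": name, "estimate": est, "ci_low": lo, "ci_high": hi}
            for name, (est, lo, hi) in self.metrics.items()
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "metrics": {
                name: {"estimate": est, "ci_low": lo, "ci_high": hi}
                for name, (est, lo, hi) in self.metrics.items()
            },
            "n_samples": self.n_samples,
            "prevalence": self.prevalence,
            "cutoff": self.cutoff,
            "n_bootstrap": self.n_bootstrap,
            "subset": self.subset,
        }


def evaluate_score(
    norm: NormalizedMatrix,
    model: MiRScoreModel,
    annotations: pd.DataFrame,
    subset: str = "wild_type_only",
    n_reps: int = 2000,
    seed: int = 0,
    cutoff_policy: str = "refit",
    refit_cutoff_in_bootstrap: bool = True,
) -> DiagnosticPerformance:
    """Full diagnostic evaluation of a fitted miR-score on a sample subset.

    ``subset`` is ``"wild_type_only"`` (mutation-negative samples, the
    training condition) or ``"all"``.  ``cutoff_policy="refit"`` re-derives
    the Youden cutoff on the evaluated subset (default); ``"model"`` reuses
    ``model.cutoff``.  NPV and PPV depend on the subset's malignancy
    prevalence, which is reported alongside.
    """
    if subset not in ("wild_type_only", "all"):
        raise DiagnosticsError(f"unknown subset {subset!r}")
    if cutoff_policy not in ("refit", "model"):
        raise DiagnosticsError(f"unknown cutoff_policy {cutoff_policy!r}")
    ann = annotations[annotations["sample_id"].isin(norm.sample_ids)]
    if subset == "wild_type_only":
        ann = ann[ann["mutation_status"] == "wild_type"]
    if ann.empty:
        raise DiagnosticsError(f"subset {subset!r} contains no samples")
    sample_ids = ann["sample_id"].tolist()
    scores = compute_score(norm, model.marker_ids).loc[sample_ids]
    labels = label_malignancy(ann).loc[sample_ids]

    curve = roc_curve(scores, labels, model.orientation)
    if cutoff_policy == "model":
        if model.cutoff is None:
            raise DiagnosticsError("cutoff_policy='model' but model has no cutoff")
        cut = float(model.cutoff)
    else:
        cut = curve.youden_cutoff
    table = contingency_at_cutoff(scores, labels, cut, model.orientation)
    point = performance_from_contingency(table)
    point["auc"] = curve.auc  # full-curve AUC, not the single-point area
    cis = bootstrap_ci(
        scores,
        labels,
        n_reps=n_reps,
        seed=seed,
        orientation=model.orientation,
        refit_cutoff=refit_cutoff_in_bootstrap,
        cutoff=cut,
    )
    metrics = {}
    for name in METRIC_NAMES:
        lo, hi = cis[name]
        est = point[name]
        if np.isfinite(est) and not (lo <= est <= hi):
            logger.info(
                "percentile CI for %s does not bracket the point estimate "
                "(%.3f outside [%.3f, %.3f])",
                name,
                est,
                lo,
                hi,
            )
        metrics[name] = (est, lo, hi)
    y = _as_bool_labels(labels)
    return DiagnosticPerformance(
        metrics=metrics,
        n_samples=len(sample_ids),
        prevalence=float(y.mean()),
        cutoff=cut,
        n_bootstrap=n_reps,
        subset=subset,
    )
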