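"""Digital-count preprocessing: QC exclusion, top-k normalization, filtering, PCA.

The normalization implemented here is the "biological" normalization of
nCounter-style miRNA panels: each sample is rescaled so that the arithmetic
mean of its *k* most highly expressed endogenous miRNAs (default *k* = 100)
equals the grand mean of that quantity across samples.  Control probes
(positive, negative, ligation) never enter the normalization, the log
transform, the filter, or the PCA — they are dropped at the normalization
step.

Expression is analyzed on the log2 scale after adding a small offset
(default 0.1) to the normalized count, so that zero counts map to
``log2(0.1)`` rather than −∞.

The expression filter keeps a miRNA when either

* (a) its mean log2 expression exceeds ``mean_threshold`` (default 4,
  strict inequality), or
* (b) its mean is at or below the threshold but its unbiased sample
  variance is at least ``var_multiplier`` (default 1.5) times its own mean
  log2 expression.

Rule (b)'s reference value is configurable: ``var_reference="own_mean"``
(default, the literal reading) compares against that miRNA's own mean,
``"mean_variance"`` against the average variance over all miRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .cohort_io import CountMatrix, _sep_for

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    """Raised when a preprocessing contract is violated."""


@dataclass
class NormalizedMatrix:
    """Endogenous counts after top-k normalization, QC-passing samples only.

    ``log2_expr`` is filled by :func:`log_transform`; ``counts`` stays on the
    normalized linear scale.
    """

    counts: pd.DataFrame  # miRNA x sample, normalized counts
    norm_factors: pd.Series  # per-sample scaling factor
    top_k: int
    log2_expr: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    def write_log2(self, path) -> None:
        if self.log2_expr is None:
            raise PreprocessError("log2_expr not computed; call log_transform first")
        out = self.log2_expr.copy()
        out.index.name = "mirna_id"
        out.to_csv(path, sep=_sep_for(path), float_format="%.10g")


def read_log2_matrix(path) -> NormalizedMatrix:
    """Load a previously written log2 expression table.

    Normalization factors are not recoverable from the log2 table; a unit
    factor is recorded for each sample.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    return NormalizedMatrix(
        counts=2.0**df,
        norm_factors=pd.Series(1.0, index=df.columns),
        top_k=0,
        log2_expr=df,
    )


def qc_filter(matrix: CountMatrix, annotations: pd.DataFrame) -> CountMatrix:
    """Drop samples whose QC flag is not ``pass``.

    Every sample in the matrix must be annotated.  Removals are logged with
    the failure reason; removing every sample is an error.
    """
    ann = annotations.set_index("sample_id")
    missing = [s for s in matrix.sample_ids if s not in ann.index]
    if missing:
        raise PreprocessError(f"samples without annotation: {missing}")
    keep = []
    for sample in matrix.sample_ids:
        flag = ann.loc[sample, "qc_flag"]
        if flag == "pass":
            keep.append(sample)
        else:
            logger.info("QC exclusion: sample %s removed (%s)", sample, flag)
    if not keep:
        raise PreprocessError("QC filter removed every sample")
    return matrix.subset_samples(keep)


def normalize_top_k(matrix: CountMatrix, k: int = 100) -> NormalizedMatrix:
    """Top-k normalization on endogenous probes.

    Per sample *i*, let ``m_i`` be the arithmetic mean of its *k* largest
    endogenous counts; the scaling factor is ``mean_j(m_j) / m_i`` and all
    endogenous counts of sample *i* are multiplied by it.  Ties at the k-th
    largest count are immaterial to the mean because tied values are equal;
    the selection itself is deterministic (count descending, probe order as
    given).
    """
    endo = matrix.endogenous()
    if endo.shape[0] < k:
        raise PreprocessError(
            f"top-{k} normalization needs at least {k} endogenous miRNAs, "
            f"found {endo.shape[0]}"
        )
    values = endo.to_numpy(dtype=float)
    top_means = np.sort(values, axis=0)[-k:, :].mean(axis=0)
    zero = np.flatnonzero(top_means <= 0)
    if zero.size:
        raise PreprocessError(
            f"sample {endo.columns[zero[0]]!r} has zero top-{k} mean; cannot normalize"
        )
    grand = top_means.mean()
    factors = pd.Series(grand / top_means, index=endo.columns, name="norm_factor")
    normalized = endo.mul(factors, axis=1)
    return NormalizedMatrix(counts=normalized, norm_factors=factors, top_k=k)


def log_transform(norm: NormalizedMatrix, offset: float = 0.1) -> NormalizedMatrix:
    """Fill ``log2_expr = log2(normalized count + offset)``.

    The offset is added on the linear scale before the logarithm so zero
    counts stay finite.
    """
    if offset <= 0:
        raise PreprocessError("offset must be positive")
    if (norm.counts.to_numpy() < 0).any():
        raise PreprocessError("normalized counts must be nonnegative")
    return NormalizedMatrix(
        counts=norm.counts,
        norm_factors=norm.norm_factors,
        top_k=norm.top_k,
        log2_expr=np.log2(norm.counts + offset),
    )


@dataclass
class FilterReport:
    """Outcome of the two-criterion expression filter."""

    table: pd.DataFrame  # mirna_id-indexed: mean, variance, rule in {a,b,none}
    kept_ids: list[str] = field(default_factory=list)
    dropped_ids: list[str] = field(default_factory=list)
    rule_a_count: int = 0
    rule_b_count: int = 0

    def write(self, path) -> None:
        out = self.table.copy()
        out.index.name = "mirna_id"
        out.to_csv(path, sep=_sep_for(path), float_format="%.10g")


def filter_mirnas(
    norm: NormalizedMatrix,
    mean_threshold: float = 4.0,
    var_multiplier: float = 1.5,
    var_reference: str = "own_mean",
) -> FilterReport:
    """Apply the expression/variance filter to the log2 matrix.

    Rules (a) and (b) are disjoint by construction: (b) is only evaluated
    for miRNAs failing (a).  Requires at least two samples (unbiased sample
    variance).
    """
    if norm.log2_expr is None:
        raise PreprocessError("log2_expr not computed; call log_transform first")
    if norm.log2_expr.shape[1] < 2:
        raise PreprocessError("variance filter needs at least 2 samples")
    if var_reference not in ("own_mean", "mean_variance"):
        raise PreprocessError(f"unknown var_reference {var_reference!r}")
    means = norm.log2_expr.mean(axis=1)
    variances = norm.log2_expr.var(axis=1, ddof=1)
    rule_a = means > mean_threshold
    reference = means if var_reference == "own_mean" else variances.mean()
    rule_b = ~rule_a & (variances >= var_multiplier * reference)
    rule = pd.Series("none", index=means.index)
    rule[rule_a] = "a"
    rule[rule_b] = "b"
    table = pd.DataFrame(
        {"mean_log2": means, "variance": variances, "rule": rule, "kept": rule != "none"}
    )
    kept = table.index[table["kept"]].tolist()
    return FilterReport(
        table=table,
        kept_ids=kept,
        dropped_ids=table.index[~table["kept"]].tolist(),
        rule_a_count=int(rule_a.sum()),
        rule_b_count=int(rule_b.sum()),
    )


@dataclass
class PCASummary:
    """Variance-explained fractions and per-sample scores of a centered PCA."""

    explained_fraction: np.ndarray
    scores: pd.DataFrame  # sample x component


def pca_summary(norm: NormalizedMatrix, mirna_ids=None) -> PCASummary:
    """Centered PCA of samples over the (optionally filtered) log2 matrix.

    Fractions sum to 1 over the full component set.  A matrix with zero
    total variance cannot be decomposed and raises.
    """
    if norm.log2_expr is None:
        raise PreprocessError("log2_expr not computed; call log_transform first")
    expr = norm.log2_expr if mirna_ids is None else norm.log2_expr.loc[list(mirna_ids)]
    if expr.shape[0] < 2 or expr.shape[1] < 2:
        raise PreprocessError("PCA needs at least 2 miRNAs and 2 samples")
    X = expr.to_numpy(dtype=float).T  # samples as observations
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise PreprocessError("constant matrix: no variance to decompose")
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    frac = pca.explained_variance_ratio_
    columns = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCASummary(
        explained_fraction=frac,
        scores=pd.DataFrame(scores, index=expr.columns, columns=columns),
    )
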