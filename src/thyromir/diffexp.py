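"""Two-group moderated differential expression with empirical-Bayes variance shrinkage.

The statistic is the moderated t: per-miRNA pooled within-group variances
s² are shrunk toward a prior variance s0² estimated by fitting a scaled F
distribution to the observed variances (moment matching on the log scale,
with the trigamma function inverted by Newton iteration).  The posterior
variance is

    s_post² = (d0·s0² + d·s²) / (d0 + d),      d = n1 + n2 − 2,

and the moderated t = log2FC / (s_post·sqrt(1/n1 + 1/n2)) is referred to a
t distribution on d0 + d degrees of freedom (standard normal when d0 = ∞).
Setting d0 = 0 disables moderation and recovers the ordinary pooled
two-sample t exactly.

Marker selection uses *raw* P-values (P < 0.05) together with an absolute
log2 fold change above 2: in small cohorts no miRNA may survive FDR
adjustment, and the score construction is explicitly defined on the
unadjusted criterion.  Benjamini-Hochberg adjusted P-values are still
reported for every miRNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix

VARIANCE_FLOOR = 1e-8


class DiffExpError(ValueError):
    pass


@dataclass
class EBPrior:
    """Empirical-Bayes prior on residual variances: s² ~ s0²·F(d, d0)."""

    d0: float  # prior degrees of freedom, may be math.inf
    s0_sq: float  # prior variance

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise DiffExpError(f"prior degrees of freedom must be positive, got {self.d0}")
        if not self.s0_sq > 0:
            raise DiffExpError(f"prior variance must be positive, got {self.s0_sq}")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        raise DiffExpError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def estimate_eb_prior(
    sample_variances, residual_df: float, variance_floor: float = VARIANCE_FLOOR
) -> EBPrior:
    """Estimate (d0, s0²) from per-miRNA sample variances.

    Matches the first two moments of the log variances against a scaled F
    distribution with ``residual_df`` numerator degrees of freedom:

        e_g = log s²_g − ψ(d/2) + log(d/2)
        var(e) − ψ'(d/2) = ψ'(d0/2)   →  d0 by trigamma inversion
        s0² = exp( mean(e) + ψ(d0/2) − log(d0/2) )

    When the empirical spread of log variances does not exceed what sampling
    alone would produce (var(e) ≤ ψ'(d/2)), the prior degrees of freedom are
    infinite and every variance is shrunk fully to s0², the arithmetic mean
    of the sample variances (the convention of the reference empirical-Bayes
    implementation, which this function reproduces to numerical precision).
    """
    x = np.asarray(sample_variances, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DiffExpError("need at least two sample variances")
    if residual_df < 1:
        raise DiffExpError("residual_df must be >= 1")
    if np.any(x < 0):
        raise DiffExpError("negative sample variance encountered")
    x = np.maximum(x, variance_floor)
    half_d = residual_df / 2.0
    e = np.log(x) - digamma(half_d) + math.log(half_d)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, half_d))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - math.log(d0 / 2.0)))
        return EBPrior(d0=d0, s0_sq=s0_sq)
    return EBPrior(d0=math.inf, s0_sq=float(x.mean()))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DiffExpError("P-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moderated_t_test(
    log2_expr: pd.DataFrame,
    baseline_samples,
    case_samples,
    prior: EBPrior | None = None,
    d0_override: float | None = None,
    variance_floor: float = VARIANCE_FLOOR,
) -> pd.DataFrame:
    """Per-miRNA moderated t-test of case vs baseline log2 expression.

    ``log2fc = mean_case − mean_baseline``; a negative value means
    down-regulation in the case group.  ``prior`` defaults to
    :func:`estimate_eb_prior` on the pooled variances; ``d0_override`` forces
    the prior degrees of freedom (0 disables moderation entirely).

    Returns a DataFrame indexed by miRNA with columns ``mean_baseline``,
    ``mean_case``, ``log2fc``, ``t``, ``p``, ``p_adj``.
    """
    baseline = list(baseline_samples)
    case = list(case_samples)
    n1, n2 = len(baseline), len(case)
    if n1 < 2 or n2 < 2:
        raise DiffExpError(f"each group needs >= 2 samples (got {n1} and {n2})")
    missing = [s for s in baseline + case if s not in log2_expr.columns]
    if missing:
        raise DiffExpError(f"samples absent from expression matrix: {missing}")
    x1 = log2_expr.loc[:, baseline].to_numpy(dtype=float)
    x2 = log2_expr.loc[:, case].to_numpy(dtype=float)
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    lfc = m2 - m1
    d = n1 + n2 - 2
    pooled = ((n1 - 1) * x1.var(axis=1, ddof=1) + (n2 - 1) * x2.var(axis=1, ddof=1)) / d
    pooled = np.maximum(pooled, variance_floor)

    if d0_override is not None:
        d0 = float(d0_override)
        if d0 < 0:
            raise DiffExpError("d0_override must be >= 0")
        s0_sq = 1.0  # irrelevant when d0 == 0; a prior is required otherwise
        if d0 > 0:
            if prior is None:
                prior = estimate_eb_prior(pooled, d, variance_floor)
            s0_sq = prior.s0_sq
    else:
        if prior is None:
            prior = estimate_eb_prior(pooled, d, variance_floor)
        d0, s0_sq = prior.d0, prior.s0_sq

    if math.isinf(d0):
        s_post = np.full_like(pooled, s0_sq)
        df_total = math.inf
    else:
        s_post = (d0 * s0_sq + d * pooled) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s_post * (1.0 / n1 + 1.0 / n2))
    t = lfc / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "mean_baseline": m1,
            "mean_case": m2,
            "log2fc": lfc,
            "t": t,
            "p": p,
            "p_adj": bh_adjust(p),
        },
        index=log2_expr.index,
    )


def select_markers(
    results: pd.DataFrame, p_max: float = 0.05, min_abs_log2fc: float = 2.0
) -> pd.DataFrame:
    """Marker-selection rule: raw P < ``p_max`` and |log2FC| > ``min_abs_log2fc``.

    Both inequalities are strict.  Returns the selected rows (possibly
    empty — a legitimate outcome) sorted by P, with a ``direction`` column
    (``down`` = lower in the case group).
    """
    if results.empty:
        raise DiffExpError("empty differential-expression table")
    mask = (results["p"] < p_max) & (results["log2fc"].abs() > min_abs_log2fc)
    selected = results.loc[mask].sort_values("p").copy()
    selected["direction"] = np.where(selected["log2fc"] < 0, "down", "up")
    return selected


def differential_expression(
    norm: NormalizedMatrix,
    annotations: pd.DataFrame,
    baseline_histology: str = "FA",
    case_histology: str = "FV-PTC",
    wild_type_only: bool = True,
    prior: EBPrior | None = None,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Differential expression between two histologies on the fitted cohort.

    By default the comparison is restricted to mutation-negative samples
    (wild-type FA baseline vs wild-type FV-PTC), the design under which the
    markers are defined; mutated samples and NIFTPs enter only at scoring
    time.
    """
    if norm.log2_expr is None:
        raise DiffExpError("normalized matrix has no log2 expression")
    ann = annotations.set_index("sample_id")
    ann = ann.loc[[s for s in norm.sample_ids if s in ann.index]]
    if wild_type_only:
        ann = ann[ann["mutation_status"] == "wild_type"]
    baseline = ann.index[ann["histology"] == baseline_histology].tolist()
    case = ann.index[ann["histology"] == case_histology].tolist()
    return moderated_t_test(
        norm.log2_expr, baseline, case, prior=prior, d0_override=d0_override
    )
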