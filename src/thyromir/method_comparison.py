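"""RT-PCR cross-validation: 2^-ΔΔCt relative quantification and Passing-Bablok regression.

Relative expression from qPCR triplicates follows the comparative-Ct
scheme: per sample, ΔCt = mean Ct(target) − mean Ct(reference assay);
ΔΔCt subtracts the calibrator sample's ΔCt; the relative quantity is
rq = 2^−ΔΔCt (the calibrator's rq is exactly 1).

Method agreement between the digital-count platform (reference method,
x-axis) and RT-PCR (test method, y-axis) is assessed by Passing-Bablok
regression — a rank-based fit with no distributional assumption.  The
slope is the shifted median of all pairwise slopes (pairs with tied x are
undefined and skipped; slopes equal to −1 are discarded; the median index
is offset by the number of slopes below −1), the intercept is
median(y − slope·x), and confidence bounds come from the rank-based normal
approximation.  A slope CI excluding 1 flags a proportional difference
between the methods; an intercept CI excluding 0 flags a constant
difference.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import NormalizedMatrix


class MethodComparisonError(ValueError):
    pass


CT_COLUMNS = ("sample_id", "assay_id", "ct1", "ct2", "ct3")


def read_ct_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise MethodComparisonError(f"Ct table missing column(s): {missing}")
    return df


def _mean_ct(row: pd.Series) -> float:
    values = row[["ct1", "ct2", "ct3"]].to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise MethodComparisonError(
            f"no finite Ct for sample {row['sample_id']!r}, assay {row['assay_id']!r}"
        )
    if (finite <= 0).any():
        raise MethodComparisonError(
            f"nonpositive Ct for sample {row['sample_id']!r}, assay {row['assay_id']!r}"
        )
    if finite.size < 3:
        warnings.warn(
            f"sample {row['sample_id']!r}, assay {row['assay_id']!r}: "
            f"only {finite.size} replicate(s) available",
            stacklevel=2,
        )
    return float(finite.mean())


def ddct_relative_expression(
    ct_table: pd.DataFrame,
    target_assay: str,
    reference_assay: str,
    calibrator_sample: str,
) -> pd.DataFrame:
    """2^-ΔΔCt relative expression of one target assay across samples.

    Triplicates are averaged arithmetically.  Every sample must carry both
    the target and the reference assay; the calibrator sample anchors
    rq = 1.
    """
    missing_cols = [c for c in CT_COLUMNS if c not in ct_table.columns]
    if missing_cols:
        raise MethodComparisonError(f"Ct table missing column(s): {missing_cols}")
    means: dict[tuple[str, str], float] = {}
    for _, row in ct_table.iterrows():
        means[(str(row["sample_id"]), str(row["assay_id"]))] = _mean_ct(row)
    samples = [
        s for (s, a) in means if a == target_assay
    ]
    if not samples:
        raise MethodComparisonError(f"no rows for target assay {target_assay!r}")
    if calibrator_sample not in samples:
        raise MethodComparisonError(
            f"calibrator sample {calibrator_sample!r} has no {target_assay!r} triplicate"
        )
    rows = []
    for s in samples:
        if (s, reference_assay) not in means:
            raise MethodComparisonError(
                f"sample {s!r} lacks the reference assay {reference_assay!r}"
            )
        rows.append(
            {
                "sample_id": s,
                "assay_id": target_assay,
                "mean_ct_target": means[(s, target_assay)],
                "mean_ct_reference": means[(s, reference_assay)],
                "delta_ct": means[(s, target_assay)] - means[(s, reference_assay)],
            }
        )
    out = pd.DataFrame(rows)
    calibrator_dct = float(
        out.loc[out["sample_id"] == calibrator_sample, "delta_ct"].iloc[0]
    )
    out["delta_delta_ct"] = out["delta_ct"] - calibrator_dct
    out["rq"] = 2.0 ** (-out["delta_delta_ct"])
    return out


@dataclass
class PBResult:
    """Passing-Bablok fit with rank-based confidence bounds and agreement flags."""

    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    n_pairs: int
    proportional_difference: bool  # slope CI excludes 1
    constant_difference: bool  # intercept CI excludes 0

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_ci": list(self.slope_ci),
            "intercept": self.intercept,
            "intercept_ci": list(self.intercept_ci),
            "n_pairs": self.n_pairs,
            "proportional_difference": self.proportional_difference,
            "constant_difference": self.constant_difference,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    slopes = []
    for i, j in itertools.combinations(range(x.size), 2):
        dx = x[j] - x[i]
        if dx == 0:
            continue  # undefined slope (tied x): skipped
        s = (y[j] - y[i]) / dx
        if s == -1.0:
            continue  # exactly -1 is discarded by the estimator
        slopes.append(s)
    return np.sort(np.asarray(slopes, dtype=float))


def passing_bablok_fit(x, y, alpha: float = 0.05, ci_method: str = "analytic") -> PBResult:
    """Passing-Bablok regression of test-method y on reference-method x.

    ``ci_method="analytic"`` (default) uses the rank-based normal
    approximation; ``"bootstrap"`` resamples pairs (1999 replicates,
    percentile bounds), a fallback for very small n where the approximation
    is coarse.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise MethodComparisonError("x and y must be 1-D and equally long")
    if x.size < 3:
        raise MethodComparisonError("Passing-Bablok needs at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise MethodComparisonError("x and y must be finite")
    if np.unique(x).size == 1:
        raise MethodComparisonError("all x values identical: slope undefined")

    slopes = _pairwise_slopes(x, y)
    n_slopes = slopes.size
    if n_slopes == 0:
        raise MethodComparisonError("no defined pairwise slopes")
    k_offset = int((slopes < -1.0).sum())

    def shifted_median(offset: int) -> float:
        # 1-based index arithmetic, clipped into range
        if n_slopes % 2 == 1:
            idx = (n_slopes + 1) // 2 + offset
            return float(slopes[np.clip(idx - 1, 0, n_slopes - 1)])
        i1 = np.clip(n_slopes // 2 + offset - 1, 0, n_slopes - 1)
        i2 = np.clip(n_slopes // 2 + 1 + offset - 1, 0, n_slopes - 1)
        return float(0.5 * (slopes[i1] + slopes[i2]))

    slope = shifted_median(k_offset)

    n = x.size
    if ci_method == "analytic":
        z = stats.norm.ppf(1 - alpha / 2)
        w = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
        m1 = int(round((n_slopes - w) / 2.0))
        m2 = n_slopes - m1 + 1
        lo_idx = np.clip(m1 + k_offset - 1, 0, n_slopes - 1)
        hi_idx = np.clip(m2 + k_offset - 1, 0, n_slopes - 1)
        slope_lo = float(slopes[lo_idx])
        slope_hi = float(slopes[hi_idx])
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(0)
        reps = []
        for _ in range(1999):
            idx = rng.integers(0, n, size=n)
            xs, ys = x[idx], y[idx]
            if np.unique(xs).size < 2:
                continue
            s = _pairwise_slopes(xs, ys)
            if s.size == 0:
                continue
            k = int((s < -1.0).sum())
            ns = s.size
            if ns % 2 == 1:
                reps.append(float(s[np.clip((ns + 1) // 2 + k - 1, 0, ns - 1)]))
            else:
                i1 = np.clip(ns // 2 + k - 1, 0, ns - 1)
                i2 = np.clip(ns // 2 + k, 0, ns - 1)
                reps.append(float(0.5 * (s[i1] + s[i2])))
        slope_lo, slope_hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        slope_lo, slope_hi = float(slope_lo), float(slope_hi)
    else:
        raise MethodComparisonError(f"unknown ci_method {ci_method!r}")

    intercept = float(np.median(y - slope * x))
    int_a = float(np.median(y - slope_hi * x))
    int_b = float(np.median(y - slope_lo * x))
    intercept_ci = (min(int_a, int_b), max(int_a, int_b))

    return PBResult(
        slope=slope,
        slope_ci=(slope_lo, slope_hi),
        intercept=intercept,
        intercept_ci=intercept_ci,
        n_pairs=n,
        proportional_difference=not (slope_lo <= 1.0 <= slope_hi),
        constant_difference=not (intercept_ci[0] <= 0.0 <= intercept_ci[1]),
    )


def compare_platforms(
    norm: NormalizedMatrix,
    rq_table: pd.DataFrame,
    marker: str,
    y_mode: str = "rq",
    alpha: float = 0.05,
    ci_method: str = "analytic",
) -> PBResult:
    """Passing-Bablok comparison of RT-PCR against the count platform.

    x is the marker's log2 expression on the count platform (reference
    method); y is the RT-PCR relative expression of the same samples, on
    the linear rq scale by default or log2(rq) with ``y_mode="log2_rq"``.
    """
    if norm.log2_expr is None:
        raise MethodComparisonError("normalized matrix has no log2 expression")
    if y_mode not in ("rq", "log2_rq"):
        raise MethodComparisonError(f"unknown y_mode {y_mode!r}")
    if marker not in norm.log2_expr.index:
        raise MethodComparisonError(f"marker {marker!r} absent from expression matrix")
    rq = rq_table[rq_table["assay_id"] == marker].set_index("sample_id")["rq"]
    shared = [s for s in norm.sample_ids if s in rq.index]
    if len(shared) < 3:
        raise MethodComparisonError(
            f"need >= 3 samples shared between platforms, found {len(shared)}"
        )
    x = norm.log2_expr.loc[marker, shared].to_numpy(dtype=float)
    y = rq.loc[shared].to_numpy(dtype=float)
    if y_mode == "log2_rq":
        y = np.log2(y)
    return passing_bablok_fit(x, y, alpha=alpha, ci_method=ci_method)
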