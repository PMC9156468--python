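"""Shared fixtures: simulated cohorts and a multi-seed recovery study."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thyromir as tm

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


def preprocess_cohort(matrix, annotations, k: int = 100):
    """QC → normalize → log → filter; returns (filtered matrix, report)."""
    analyzed = tm.qc_filter(matrix, annotations)
    norm = tm.log_transform(tm.normalize_top_k(analyzed, k))
    report = tm.filter_mirnas(norm)
    filtered = tm.NormalizedMatrix(
        counts=norm.counts.loc[report.kept_ids],
        norm_factors=norm.norm_factors,
        top_k=norm.top_k,
        log2_expr=norm.log2_expr.loc[report.kept_ids],
    )
    return filtered, report, norm


@pytest.fixture(scope="session")
def default_cohort():
    """One default 60-sample cohort (fixed seed) with its truth record."""
    config = tm.CohortConfig(seed=7)
    matrix, annotations, truth = tm.generate_cohort(config)
    return config, matrix, annotations, truth


@pytest.fixture(scope="session")
def preprocessed_default(default_cohort):
    _, matrix, annotations, _ = default_cohort
    return preprocess_cohort(matrix, annotations)


@dataclass
class SeedStudyResult:
    kept_counts: np.ndarray
    both_markers_selected: np.ndarray  # bool per seed
    marker_log2fc: np.ndarray  # mean over the two markers, per seed
    marker_max_p_rank: np.ndarray  # worse of the two markers' P ranks
    wildtype_auc: np.ndarray


@pytest.fixture(scope="session")
def marker_recovery_study() -> SeedStudyResult:
    """Fifty independent default cohorts pushed through DE and scoring.

    Summarizes how often the planted markers satisfy the selection rule and
    how the miR-score separates wild-type FA from FV-PTC.
    """
    n_seeds = 50
    kept, both, lfc, rank, auc = [], [], [], [], []
    for seed in range(n_seeds):
        config = tm.CohortConfig(seed=seed)
        matrix, annotations, _ = tm.generate_cohort(config)
        filtered, report, _ = preprocess_cohort(matrix, annotations)
        de = tm.differential_expression(filtered, annotations)
        selected = tm.select_markers(de)
        markers = list(config.marker_ids)
        kept.append(len(report.kept_ids))
        both.append(set(markers) <= set(selected.index))
        lfc.append(float(de.loc[markers, "log2fc"].mean()))
        rank.append(float(de["p"].rank(method="min").loc[markers].max()))
        model = tm.MiRScoreModel(marker_ids=tuple(markers))
        perf = tm.evaluate_score(
            filtered, model, annotations, subset="wild_type_only", n_reps=10, seed=0
        )
        auc.append(perf.metrics["auc"][0])
    return SeedStudyResult(
        kept_counts=np.array(kept),
        both_markers_selected=np.array(both),
        marker_log2fc=np.array(lfc),
        marker_max_p_rank=np.array(rank),
        wildtype_auc=np.array(auc),
    )
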