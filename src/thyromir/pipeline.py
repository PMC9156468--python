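"""End-to-end orchestration of the nodule-cohort analysis.

A single :class:`PipelineConfig` drives the run: either paths to a count
matrix / annotation table (and optionally a Ct table), or a ``simulate``
block holding a :class:`~thyromir.synthetic_cohort.CohortConfig`.  The
stages mirror the analysis order: QC exclusion → top-k normalization →
log transform → expression filter → PCA summary → moderated differential
expression (wild-type FA vs wild-type FV-PTC) → marker selection →
miR-score with Youden cutoff → diagnostic evaluation on the wild-type and
all-sample subsets → optional RT-PCR method comparison.  An
annotation-only run (no counts, no simulation) produces the cross-tab and
the mutation-marker performance alone.

Every output is a TSV or JSON file under ``outdir``; a run is byte-identical
when repeated with the same config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort_io, diagnostics, diffexp, method_comparison, mirscore, preprocess
from .synthetic_cohort import (
    REFERENCE_ASSAY,
    CohortConfig,
    generate_cohort,
    generate_ct_table,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    counts_path: str | None = None
    annotations_path: str | None = None
    ct_path: str | None = None
    simulate: CohortConfig | None = None
    normalization_k: int = 100
    log_offset: float = 0.1
    mean_threshold: float = 4.0
    var_multiplier: float = 1.5
    p_max: float = 0.05
    min_abs_log2fc: float = 2.0
    n_bootstrap: int = 2000
    seed: int = 0
    evaluation_subsets: tuple[str, ...] = ("wild_type_only", "all")
    calibrator_sample: str | None = None
    pb_y_mode: str = "rq"

    def __post_init__(self) -> None:
        has_inputs = self.annotations_path is not None
        if not has_inputs and self.simulate is None:
            raise PipelineError(
                "config needs either input paths or a simulate block"
            )
        for name in ("normalization_k", "p_max", "min_abs_log2fc", "n_bootstrap"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            cells = sim.pop("n_per_cell", None)
            if cells is not None:
                sim["n_per_cell"] = {
                    (h, m): int(n)
                    for key, n in cells.items()
                    for h, m in [tuple(key.split("|"))]
                }
            if "marker_ids" in sim:
                sim["marker_ids"] = tuple(sim["marker_ids"])
            sim = CohortConfig(**sim)
        subsets = raw.pop("evaluation_subsets", None)
        cfg = cls(
            simulate=sim,
            **({"evaluation_subsets": tuple(subsets)} if subsets else {}),
            **raw,
        )
        return cfg

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            sim = dataclasses.asdict(self.simulate)
            sim["n_per_cell"] = {f"{h}|{m}": n for (h, m), n in sim["n_per_cell"].items()}
            sim["marker_ids"] = list(sim["marker_ids"])
            d["simulate"] = sim
        d["evaluation_subsets"] = list(self.evaluation_subsets)
        return d


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return decorate


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the configured analysis; return the report bundle.

    The bundle maps stage names to in-memory results; all tabular and JSON
    outputs are also written under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config.resolved()}
    _write_json(outdir / "resolved_config.json", config.resolved())

    # ---- inputs -----------------------------------------------------------
    truth = None
    ct_table = None
    if config.simulate is not None:
        logger.info("simulating cohort (seed=%d)", config.simulate.seed)
        matrix, annotations, truth = _stage("simulate")(generate_cohort)(config.simulate)
        ct_table = generate_ct_table(config.simulate, truth)
        matrix.write(outdir / "counts.tsv")
        cohort_io.write_annotations(annotations, outdir / "annotations.tsv")
        ct_table.to_csv(outdir / "ct_table.tsv", sep="\t", index=False, float_format="%.6f")
        (outdir / "truth.json").write_text(truth.to_json() + "\n")
    else:
        annotations = _stage("read_annotations")(cohort_io.read_annotations)(
            config.annotations_path
        )
        matrix = (
            _stage("read_counts")(cohort_io.read_counts)(config.counts_path)
            if config.counts_path
            else None
        )
        if config.ct_path:
            ct_table = _stage("read_ct")(method_comparison.read_ct_table)(config.ct_path)

    # ---- annotation-side results -----------------------------------------
    crosstab = _stage("cross_tabulate")(cohort_io.cross_tabulate)(annotations)
    crosstab.write(outdir / "crosstab.tsv")
    crosstab.write(outdir / "crosstab.json")
    bundle["crosstab"] = crosstab

    mutation_table = _stage("mutation_marker")(diagnostics.mutation_contingency)(
        annotations
    )
    mutation_perf = diagnostics.performance_from_contingency(mutation_table)
    _write_json(
        outdir / "mutation_performance.json",
        {
            "contingency": dataclasses.asdict(mutation_table),
            "metrics": mutation_perf,
            "n_samples": mutation_table.total,
        },
    )
    bundle["mutation_performance"] = mutation_perf

    if matrix is None:
        logger.info("annotation-only mode: expression stages skipped")
        return bundle

    # ---- expression-side stages ------------------------------------------
    analyzed = _stage("qc_filter")(preprocess.qc_filter)(matrix, annotations)
    bundle["n_samples_analyzed"] = len(analyzed.sample_ids)

    norm = _stage("normalize")(preprocess.normalize_top_k)(
        analyzed, config.normalization_k
    )
    norm = _stage("log_transform")(preprocess.log_transform)(norm, config.log_offset)
    norm.write_log2(outdir / "log2_matrix.tsv")
    norm.norm_factors.rename("norm_factor").to_csv(
        outdir / "norm_factors.tsv", sep="\t", float_format="%.10g"
    )

    report = _stage("filter")(preprocess.filter_mirnas)(
        norm, config.mean_threshold, config.var_multiplier
    )
    report.write(outdir / "filter_report.tsv")
    bundle["filter_report"] = report

    pca = _stage("pca")(preprocess.pca_summary)(norm, report.kept_ids)
    pca.scores.round(6).to_csv(outdir / "pca_scores.tsv", sep="\t")
    _write_json(
        outdir / "pca_variance.json",
        {"explained_fraction": [round(float(f), 6) for f in pca.explained_fraction]},
    )
    bundle["pca"] = pca

    filtered = preprocess.NormalizedMatrix(
        counts=norm.counts.loc[report.kept_ids],
        norm_factors=norm.norm_factors,
        top_k=norm.top_k,
        log2_expr=norm.log2_expr.loc[report.kept_ids],
    )
    de = _stage("diffexp")(diffexp.differential_expression)(filtered, annotations)
    selected = diffexp.select_markers(de, config.p_max, config.min_abs_log2fc)
    de_out = de.copy()
    de_out["selected"] = de_out.index.isin(selected.index)
    de_out.index.name = "mirna_id"
    de_out.to_csv(outdir / "de_table.tsv", sep="\t", float_format="%.6g")
    bundle["de_table"] = de
    bundle["markers"] = selected
    if selected.empty:
        logger.info("no miRNA passed the selection rule; scoring skipped")
        _write_json(outdir / "performance.json", {"markers": [], "evaluations": {}})
        return bundle

    model = mirscore.MiRScoreModel(
        marker_ids=tuple(selected.index),
        training="wild-type FA vs wild-type FV-PTC, Youden cutoff",
    )
    scores = mirscore.compute_score(filtered, model.marker_ids)
    correlations = (
        mirscore.marker_correlations(filtered, model.marker_ids)
        if len(model.marker_ids) >= 2
        else pd.DataFrame()
    )

    evaluations = {}
    perf_json: dict = {"markers": list(model.marker_ids), "evaluations": {}}
    wt_curve = None
    for subset in config.evaluation_subsets:
        perf = _stage(f"evaluate[{subset}]")(diagnostics.evaluate_score)(
            filtered,
            model,
            annotations,
            subset=subset,
            n_reps=config.n_bootstrap,
            seed=config.seed,
        )
        evaluations[subset] = perf
        perf_json["evaluations"][subset] = perf.to_dict()
        if subset == "wild_type_only":
            model.cutoff = perf.cutoff
            wt_curve = perf
    if model.cutoff is None and evaluations:
        model.cutoff = next(iter(evaluations.values())).cutoff
    bundle["model"] = model
    bundle["evaluations"] = evaluations
    bundle["marker_correlations"] = correlations

    predicted = mirscore.apply_cutoff(scores, model)
    score_table = pd.DataFrame({"mir_score": scores, "predicted": predicted})
    score_table.index.name = "sample_id"
    score_table.round(6).to_csv(outdir / "score_table.tsv", sep="\t")
    (outdir / "model.json").write_text(model.to_json() + "\n")
    if not correlations.empty:
        perf_json["marker_correlations"] = correlations.round(6).to_dict("records")
    _write_json(outdir / "performance.json", perf_json)

    # ---- method comparison ------------------------------------------------
    if ct_table is not None:
        calibrator = config.calibrator_sample
        shared = [
            s for s in filtered.sample_ids if s in set(ct_table["sample_id"])
        ]
        if calibrator is None and shared:
            calibrator = shared[0]
        pb_out = {}
        for marker in model.marker_ids:
            if marker not in set(ct_table["assay_id"]):
                continue
            rq = _stage("ddct")(method_comparison.ddct_relative_expression)(
                ct_table, marker, REFERENCE_ASSAY, calibrator
            )
            pb = _stage("passing_bablok")(method_comparison.compare_platforms)(
                filtered, rq, marker, y_mode=config.pb_y_mode
            )
            pb_out[marker] = pb.to_dict()
            bundle.setdefault("method_comparison", {})[marker] = pb
        if pb_out:
            _write_json(outdir / "method_comparison.json", pb_out)

    return bundle
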