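"""Synthetic cohort generator: digital counts, annotations, qPCR Ct tables, truth.

No raw expression data were deposited for the cohort this pipeline targets,
so every downstream stage is exercised against simulated data with the same
statistical structure:

* 60 nodules split over histology × mutation cells (defaults: FA 22 wt +
  2 mutated, FV-PTC 16 wt + 14 mutated, NIFTP 3 wt + 3 mutated);
* 798 endogenous miRNA probes plus 30 controls; counts are negative
  binomial (Gamma-Poisson) around per-class means, with log-normal
  library-size variation and an additive non-specific background so that
  normalization and the expression filter are both non-trivial;
* two planted marker miRNAs down-regulated in FV-PTC relative to FA
  (default −2.5 log2 units, beyond the |log2FC| > 2 selection bound), with
  an extra repression in mutation-positive samples; wild-type NIFTPs keep
  FA-level marker expression while mutated NIFTPs sit at the (further
  repressed) FV-PTC level;
* two QC failures: one low-RNA-content sample (globally depressed counts)
  and one internal-positive-control failure (flagged only) — the cohort
  analyzes to 58 samples.

The generator also emits qPCR Ct triplicates for the markers and a
reference small-RNA assay.  Ct falls linearly with true log2 expression;
the proportionality ``ct_slope`` deliberately defaults to 0.2 to emulate
the imperfect count-platform/RT-PCR agreement seen in practice (a
Passing-Bablok slope well below 1); set it to 1 for distortion-free
tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import CountMatrix, validate_annotations

DEFAULT_CELLS: dict[tuple[str, str], int] = {
    ("FA", "wild_type"): 22,
    ("FA", "mutated"): 2,
    ("FV-PTC", "wild_type"): 16,
    ("FV-PTC", "mutated"): 14,
    ("NIFTP", "wild_type"): 3,
    ("NIFTP", "mutated"): 3,
}

RAS_LIKE_MUTATIONS = (
    "NRAS p.Q61R",
    "NRAS p.Q61K",
    "HRAS p.Q61R",
    "KRAS p.G12V",
    "BRAF p.K601E",
)

REFERENCE_ASSAY = "RNU6-1"


class SyntheticCohortError(ValueError):
    pass


@dataclass
class CohortConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    n_per_cell: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_CELLS)
    )
    n_endogenous: int = 798
    n_controls: int = 30
    #: baseline abundance model: ``n_expressed`` miRNAs (markers included)
    #: get log2 mean counts drawn log-uniformly over ``expressed_log2_range``
    #: — a long-tailed count distribution spanning ~4 decades — while the
    #: rest sit near the non-specific background, below the expression
    #: filter; ~100 expressed probes echoes the scale of a real panel.
    n_expressed: int = 100
    expressed_log2_range: tuple[float, float] = (4.5, 14.0)
    unexpressed_log2_range: tuple[float, float] = (0.0, 2.5)
    #: additive non-specific background (counts) on every probe
    background_mean: float = 8.0
    nb_dispersion: float = 0.1
    libsize_log_sd: float = 0.3
    marker_ids: tuple[str, ...] = ("hsa-miR-7-5p", "hsa-miR-548ar-5p")
    marker_baseline_log2: float = 10.0
    marker_log2fc: float = -2.5
    mutated_extra_shift: float = -1.0
    #: per-sample biological spread of true marker log2 expression
    marker_biological_sd: float = 0.4
    n_qc_failures: int = 2
    low_content_scale: float = 0.05
    #: Ct falls by ct_slope cycles per unit of true log2 expression; 1 means
    #: perfect proportionality between the platforms, the 0.2 default plants
    #: a strong proportional distortion.
    ct_slope: float = 0.2
    ct_noise_sd: float = 0.15
    ct_target_intercept: float = 32.0
    ct_reference_ct: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_cell.values()):
            raise SyntheticCohortError("cell sizes must be nonnegative")
        if len(self.marker_ids) > self.n_endogenous:
            raise SyntheticCohortError("more markers than endogenous miRNAs")
        if not len(self.marker_ids) <= self.n_expressed <= self.n_endogenous:
            raise SyntheticCohortError(
                "n_expressed must lie between the marker count and n_endogenous"
            )
        if self.nb_dispersion <= 0:
            raise SyntheticCohortError("negative-binomial dispersion must be positive")
        if self.n_qc_failures < 0:
            raise SyntheticCohortError("n_qc_failures must be nonnegative")

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_cell.values())


@dataclass
class TruthRecord:
    """Generating truth for a simulated cohort.

    ``class_log2_means`` holds each marker's true mean log2 expression per
    (histology, mutation_status) cell; ``sample_true_log2`` the realized
    per-sample true values (class mean + biological noise, before
    measurement noise); ``malignant`` the per-sample truth label.
    """

    marker_ids: tuple[str, ...]
    class_log2_means: dict[str, dict[tuple[str, str], float]]
    sample_true_log2: pd.DataFrame  # markers x samples
    malignant: pd.Series  # sample -> "benign"/"malignant"
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "marker_ids": list(self.marker_ids),
                "class_log2_means": {
                    m: {f"{h}|{mu}": v for (h, mu), v in cells.items()}
                    for m, cells in self.class_log2_means.items()
                },
                "sample_true_log2": {
                    m: self.sample_true_log2.loc[m].round(6).to_dict()
                    for m in self.sample_true_log2.index
                },
                "malignant": self.malignant.to_dict(),
                "seed": self.seed,
            },
            indent=2,
            sort_keys=True,
        )


def _marker_shift(config: CohortConfig, histology: str, mutation: str) -> float:
    """True marker log2 shift relative to the FA wild-type baseline."""
    shift = 0.0
    if histology == "FV-PTC" or (histology == "NIFTP" and mutation == "mutated"):
        shift += config.marker_log2fc
    if mutation == "mutated":
        shift += config.mutated_extra_shift
    return shift


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[CountMatrix, pd.DataFrame, TruthRecord]:
    """Draw one cohort: counts, annotations and the generating truth.

    Deterministic for a fixed ``config.seed``.  QC failures are placed in
    the wild-type FA and wild-type FV-PTC cells first (one low-content, one
    positive-control failure), mirroring a cohort whose analyzable subset
    loses one sample from each comparison group.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)

    markers = list(config.marker_ids)
    n_other = config.n_endogenous - len(markers)
    mirna_ids = markers + [f"hsa-miR-sim-{i + 1:04d}" for i in range(n_other)]
    n_pos = min(6, config.n_controls)
    n_neg = min(8, max(0, config.n_controls - n_pos))
    n_lig = max(0, config.n_controls - n_pos - n_neg)
    control_ids = (
        [f"POS_{chr(65 + i)}" for i in range(n_pos)]
        + [f"NEG_{i + 1:02d}" for i in range(n_neg)]
        + [f"LIG_{i + 1:02d}" for i in range(n_lig)]
    )
    probe_class = pd.Series(
        ["endogenous"] * config.n_endogenous
        + ["positive"] * n_pos
        + ["negative"] * n_neg
        + ["ligation"] * n_lig,
        index=mirna_ids + control_ids,
    )

    # samples, grouped by (histology, mutation) cell in fixed order
    rows = []
    for (histology, mutation), n in sorted(config.n_per_cell.items()):
        for _ in range(n):
            rows.append((histology, mutation))
    n_samples = len(rows)
    if n_samples == 0:
        raise SyntheticCohortError("empty cohort")
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    annotations = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cytology": np.where(rng.random(n_samples) < 37 / 60, "TIR3A", "TIR3B"),
            "histology": [h for h, _ in rows],
            "mutation_status": [m for _, m in rows],
            "mutation_detail": [
                rng.choice(RAS_LIKE_MUTATIONS) if m == "mutated" else ""
                for _, m in rows
            ],
            "qc_flag": "pass",
        }
    )

    # baseline abundance: expressed probes (markers first) are log-uniform over
    # a wide count range; the remainder sits at/below the background level
    n_markers = len(markers)
    baseline_log2 = np.empty(config.n_endogenous)
    baseline_log2[:n_markers] = config.marker_baseline_log2
    baseline_log2[n_markers : config.n_expressed] = rng.uniform(
        *config.expressed_log2_range, config.n_expressed - n_markers
    )
    baseline_log2[config.n_expressed :] = rng.uniform(
        *config.unexpressed_log2_range, config.n_endogenous - config.n_expressed
    )

    # true per-sample marker log2 expression (class mean + biological noise)
    class_means: dict[str, dict[tuple[str, str], float]] = {m: {} for m in markers}
    for m in markers:
        for cell in config.n_per_cell:
            class_means[m][cell] = config.marker_baseline_log2 + _marker_shift(
                config, *cell
            )
    true_log2 = np.empty((len(markers), n_samples))
    for j, (histology, mutation) in enumerate(rows):
        shift = _marker_shift(config, histology, mutation)
        true_log2[:, j] = (
            config.marker_baseline_log2
            + shift
            + rng.normal(0.0, config.marker_biological_sd, len(markers))
        )

    # expected counts: 2^log2mean + background, times a library-size factor
    mean_log2 = np.tile(baseline_log2[:, None], (1, n_samples))
    mean_log2[: len(markers), :] = true_log2
    lib = rng.lognormal(0.0, config.libsize_log_sd, n_samples)
    expected = (2.0**mean_log2 + config.background_mean) * lib[None, :]

    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape, expected * config.nb_dispersion)
    endo_counts = rng.poisson(lam).astype(float)

    control_mean_counts = np.concatenate(
        [
            2.0 ** np.linspace(13, 3, n_pos) if n_pos else np.empty(0),
            np.full(n_neg, 2.0),
            np.full(n_lig, 64.0),
        ]
    )
    control_expected = control_mean_counts[:, None] * lib[None, :]
    control_counts = rng.poisson(
        rng.gamma(shape, control_expected * config.nb_dispersion)
    ).astype(float)

    counts = np.vstack([endo_counts, control_counts])

    # QC failures: alternate low_content / positive_control_failure, placed in
    # the wild-type FA then wild-type FV-PTC cells first
    def _cell_indices(histology: str) -> list[int]:
        return [
            j
            for j, (h, m) in enumerate(rows)
            if h == histology and m == "wild_type"
        ]

    candidates = _cell_indices("FA") + _cell_indices("FV-PTC") + list(range(n_samples))
    chosen: list[int] = []
    for j in candidates:
        if j not in chosen:
            chosen.append(j)
        if len(chosen) == config.n_qc_failures:
            break
    for k, j in enumerate(chosen):
        if k % 2 == 0:
            annotations.loc[j, "qc_flag"] = "low_content"
            counts[:, j] = np.rint(counts[:, j] * config.low_content_scale)
        else:
            annotations.loc[j, "qc_flag"] = "positive_control_failure"

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=probe_class.index, columns=sample_ids),
        probe_class=probe_class,
    )
    truth = TruthRecord(
        marker_ids=tuple(markers),
        class_log2_means=class_means,
        sample_true_log2=pd.DataFrame(true_log2, index=markers, columns=sample_ids),
        malignant=pd.Series(
            ["benign" if h == "FA" else "malignant" for h, _ in rows],
            index=sample_ids,
            name="malignant",
        ),
        seed=config.seed,
    )
    return matrix, validate_annotations(annotations), truth


def generate_ct_table(
    config: CohortConfig,
    truth: TruthRecord,
    sample_ids=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Triplicate qPCR Ct values for each marker and the reference assay.

    Target Ct = ``ct_target_intercept − ct_slope · true_log2`` plus Gaussian
    replicate noise; the reference assay sits at a constant level.  With
    ``ct_slope = 1`` and zero noise, ΔCt differences between samples equal
    minus their true log2-expression differences.
    """
    if truth is None:
        raise SyntheticCohortError("a TruthRecord is required")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    samples = (
        list(truth.sample_true_log2.columns) if sample_ids is None else list(sample_ids)
    )
    missing = [s for s in samples if s not in truth.sample_true_log2.columns]
    if missing:
        raise SyntheticCohortError(f"samples absent from truth: {missing}")
    rows = []
    for s in samples:
        for m in truth.marker_ids:
            center = config.ct_target_intercept - config.ct_slope * float(
                truth.sample_true_log2.loc[m, s]
            )
            ct = center + rng.normal(0.0, config.ct_noise_sd, 3)
            rows.append(
                {"sample_id": s, "assay_id": m, "ct1": ct[0], "ct2": ct[1], "ct3": ct[2]}
            )
        ref = config.ct_reference_ct + rng.normal(0.0, config.ct_noise_sd, 3)
        rows.append(
            {
                "sample_id": s,
                "assay_id": REFERENCE_ASSAY,
                "ct1": ref[0],
                "ct2": ref[1],
                "ct3": ref[2],
            }
        )
    return pd.DataFrame(rows)
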