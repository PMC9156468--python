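"""Reading, validation and cross-tabulation of cohort tables.

The pipeline's entry points are two flat delimited-text tables:

* a **count matrix** — one row per miRNA probe, first column the probe
  identifier, second column its class (``endogenous``, ``positive``,
  ``negative`` or ``ligation`` control), remaining columns raw digital
  counts for each sample;
* a **sample annotation table** — one row per nodule with its cytological
  category (TIR3A / TIR3B), histological diagnosis (FA / FV-PTC / NIFTP),
  BRAF/RAS mutation status and an instrument QC flag.

The dialect is auto-detected from the file extension: ``.csv`` is
comma-separated, anything else is tab-separated.  Native instrument (RCC)
files are deliberately not parsed; converting them to this flat layout is
the documented extension point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

PROBE_CLASSES = ("endogenous", "positive", "negative", "ligation")
CYTOLOGY_LEVELS = ("TIR3A", "TIR3B")
HISTOLOGY_LEVELS = ("FA", "FV-PTC", "NIFTP")
MUTATION_LEVELS = ("wild_type", "mutated")
QC_LEVELS = ("pass", "low_content", "positive_control_failure")

#: columns every annotation table must provide; ``mutation_detail`` is optional
REQUIRED_ANNOTATION_COLUMNS = (
    "sample_id",
    "cytology",
    "histology",
    "mutation_status",
    "qc_flag",
)

_ANNOTATION_LEVELS = {
    "cytology": CYTOLOGY_LEVELS,
    "histology": HISTOLOGY_LEVELS,
    "mutation_status": MUTATION_LEVELS,
    "qc_flag": QC_LEVELS,
}


class CohortIOError(ValueError):
    """An input table violates the cohort format contract."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round ``x`` half-up to ``ndigits`` decimals (reporting convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _sep_for(path: str | Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


@dataclass
class CountMatrix:
    """Raw digital miRNA counts with per-probe class labels.

    ``counts`` is a miRNA × sample DataFrame; ``probe_class`` is a Series
    aligned to its rows.  Validation runs on construction.
    """

    counts: pd.DataFrame
    probe_class: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise CohortIOError(f"duplicate miRNA ids: {dupes}")
        if self.counts.columns.has_duplicates:
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise CohortIOError(f"duplicate sample ids: {dupes}")
        if not self.probe_class.index.equals(self.counts.index):
            raise CohortIOError("probe_class index does not match count-matrix rows")
        bad_class = set(self.probe_class) - set(PROBE_CLASSES)
        if bad_class:
            raise CohortIOError(
                f"unknown probe class {sorted(bad_class)}; expected one of {PROBE_CLASSES}"
            )
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise CohortIOError("count matrix contains non-numeric entries")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise CohortIOError(
                f"missing count at miRNA {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise CohortIOError(
                f"negative count at miRNA {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}: {values[r, c]}"
            )

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def endogenous_ids(self) -> list[str]:
        return list(self.counts.index[self.probe_class == "endogenous"])

    def endogenous(self) -> pd.DataFrame:
        """Counts restricted to endogenous probes (controls dropped)."""
        return self.counts.loc[self.probe_class == "endogenous"]

    def subset_samples(self, sample_ids) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise CohortIOError(f"samples not in matrix: {missing}")
        return CountMatrix(self.counts.loc[:, list(sample_ids)], self.probe_class)

    def write(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "probe_class", self.probe_class)
        out.index.name = "mirna_id"
        out.to_csv(path, sep=_sep_for(path))


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count matrix from a CSV/TSV file.

    The header row holds sample ids; the first column is the miRNA id and
    the second the probe class.  Ordering is preserved from the file.
    """
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows and similar
        raise CohortIOError(f"cannot parse count matrix {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise CohortIOError(f"{path}: need a probe_class column plus at least one sample")
    if df.columns[0] != "probe_class":
        raise CohortIOError(
            f"{path}: second column must be 'probe_class', found {df.columns[0]!r}"
        )
    probe_class = df.iloc[:, 0].astype(str)
    counts = df.iloc[:, 1:]
    non_numeric = counts.columns[
        ~counts.dtypes.map(lambda t: np.issubdtype(t, np.number))
    ].tolist()
    if non_numeric:
        raise CohortIOError(f"{path}: non-numeric counts in column(s) {non_numeric}")
    counts.index = counts.index.astype(str)
    counts.index.name = None
    probe_class.index = counts.index
    probe_class.name = None
    return CountMatrix(counts, probe_class)


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Validate an annotation table in place and return it.

    Checks the required columns, the enumerated category levels and
    uniqueness of ``sample_id``.
    """
    missing = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise CohortIOError(f"annotation table missing column(s): {missing}")
    ids = annotations["sample_id"].astype(str)
    if ids.duplicated().any():
        raise CohortIOError(
            f"duplicate sample_id: {ids[ids.duplicated()].unique().tolist()}"
        )
    for col, levels in _ANNOTATION_LEVELS.items():
        bad = set(annotations[col].astype(str)) - set(levels)
        if bad:
            raise CohortIOError(
                f"unknown {col} value(s) {sorted(bad)}; expected one of {levels}"
            )
    return annotations


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample annotation table (one row per nodule)."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if "mutation_detail" not in df.columns:
        df["mutation_detail"] = ""
    return validate_annotations(df)


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    validate_annotations(annotations).to_csv(path, sep=_sep_for(path), index=False)


@dataclass
class CrossTab:
    """Sample counts cross-tabulated by cytology × histology × mutation status."""

    cells: pd.Series  # MultiIndex (cytology, histology, mutation_status) -> int
    n_total: int

    def count(self, **levels: str) -> int:
        """Number of samples matching all the given level constraints."""
        mask = np.ones(len(self.cells), dtype=bool)
        for name, value in levels.items():
            mask &= self.cells.index.get_level_values(name) == value
        return int(self.cells[mask].sum())

    def margin(self, level: str) -> pd.Series:
        return self.cells.groupby(level=level).sum()

    def fraction(self, numerator: dict, denominator: dict | None = None) -> float:
        """Unrounded fraction of samples matching ``numerator`` among those
        matching ``denominator`` (the whole cohort when omitted)."""
        denom = self.count(**denominator) if denominator else self.n_total
        if denom == 0:
            raise CohortIOError(f"empty denominator stratum: {denominator}")
        numer = self.count(**{**(denominator or {}), **numerator})
        return numer / denom

    def percent(self, numerator: dict, denominator: dict | None = None) -> float:
        """One-decimal half-up percentage, the cohort-reporting convention."""
        return round_half_up(100.0 * self.fraction(numerator, denominator), 1)

    def to_frame(self) -> pd.DataFrame:
        df = self.cells.rename("n").reset_index()
        df["percent_of_total"] = [
            round_half_up(100.0 * n / self.n_total, 1) for n in df["n"]
        ]
        return df

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "cells": [
                {
                    "cytology": cy,
                    "histology": hi,
                    "mutation_status": mu,
                    "n": int(n),
                }
                for (cy, hi, mu), n in self.cells.items()
            ],
            "margins": {
                level: {str(k): int(v) for k, v in self.margin(level).items()}
                for level in ("cytology", "histology", "mutation_status")
            },
        }

    def write(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        else:
            self.to_frame().to_csv(path, sep=_sep_for(path), index=False)


def cross_tabulate(annotations: pd.DataFrame) -> CrossTab:
    """Cross-tabulate an annotation table over all three label axes.

    Every combination of levels appears in the output, zero cells included,
    so margins are always complete.
    """
    validate_annotations(annotations)
    if len(annotations) == 0:
        raise CohortIOError("cannot cross-tabulate an empty annotation table")
    index = pd.MultiIndex.from_product(
        [CYTOLOGY_LEVELS, HISTOLOGY_LEVELS, MUTATION_LEVELS],
        names=["cytology", "histology", "mutation_status"],
    )
    observed = annotations.groupby(
        ["cytology", "histology", "mutation_status"], observed=True
    ).size()
    cells = observed.reindex(index, fill_value=0).astype(int)
    return CrossTab(cells=cells, n_total=len(annotations))
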