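"""Bundled cohort composition used for worked examples and validation.

The package ships the printed composition of a 98-nodule indeterminate
thyroid nodule cohort (cytology TIR3A/TIR3B with histological follow-up and
BRAF/RAS mutation testing).  Only the aggregate cell counts are bundled —
no per-patient measurements — so the table can be expanded into a synthetic
per-sample annotation list whose cross-tabulation reproduces the printed
marginals exactly.
"""

from __future__ import annotations

import pandas as pd

from .cohort_io import validate_annotations

#: (cytology, histology, mutation_status) -> number of nodules, 98 in total.
STUDY_COHORT_CELLS: dict[tuple[str, str, str], int] = {
    ("TIR3A", "FA", "mutated"): 2,
    ("TIR3A", "FA", "wild_type"): 32,
    ("TIR3A", "FV-PTC", "mutated"): 14,
    ("TIR3A", "FV-PTC", "wild_type"): 9,
    ("TIR3A", "NIFTP", "mutated"): 3,
    ("TIR3A", "NIFTP", "wild_type"): 3,
    ("TIR3B", "FA", "mutated"): 0,
    ("TIR3B", "FA", "wild_type"): 7,
    ("TIR3B", "FV-PTC", "mutated"): 12,
    ("TIR3B", "FV-PTC", "wild_type"): 12,
    ("TIR3B", "NIFTP", "mutated"): 1,
    ("TIR3B", "NIFTP", "wild_type"): 3,
}


def study_annotations() -> pd.DataFrame:
    """Expand the bundled cohort composition into a 98-row annotation table.

    Sample identifiers are synthetic (``N001`` …); all QC flags are ``pass``
    because the composition describes nodules, not instrument runs.
    """
    rows = []
    i = 0
    for (cytology, histology, mutation), n in STUDY_COHORT_CELLS.items():
        for _ in range(n):
            i += 1
            rows.append(
                {
                    "sample_id": f"N{i:03d}",
                    "cytology": cytology,
                    "histology": histology,
                    "mutation_status": mutation,
                    "mutation_detail": "",
                    "qc_flag": "pass",
                }
            )
    return validate_annotations(pd.DataFrame(rows))
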