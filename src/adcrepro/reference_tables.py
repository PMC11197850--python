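"""Published nine-centre reference values used as inputs.

The multi-centre MRI-linac consortium reported, for four clinical cases
(adrenal gland, pancreas, pelvic oligo metastasis, prostate) and two ROI
types each, the mean ADC (10⁻³ mm²/s) across nine centres under all eight
pre-specified calculation conditions, together with the mean percent-wise
ADC differences between b-sets (all b-values minus b ≥ 150 s/mm²),
ROI-based minus voxel-based analysis, and mean minus median. These printed
values serve as fixed inputs for summary-table checks; they are not
recomputable from public data (the underlying patient DICOM is not
deposited).
"""

from __future__ import annotations

import pandas as pd

from .reproducibility import CONDITION_ORDER, DIFFERENCE_COLUMNS

__all__ = [
    "consortium_condition_means",
    "consortium_percent_differences",
    "consortium_table1",
]

_ROWS = {
    # (case, roi): 8 condition means (10^-3 mm^2/s) + 3 percent differences
    ("adrenal", "GTV"): (1.27, 1.37, 1.21, 1.24, 0.90, 0.97, 0.88, 0.90, 32.86, 5.84, -4.91),
    ("adrenal", "VTV"): (1.26, 1.34, 1.23, 1.24, 0.88, 0.96, 0.87, 0.90, 33.69, 4.40, -4.47),
    ("pancreas", "GTV"): (0.95, 0.95, 0.88, 0.96, 0.88, 0.85, 0.81, 0.82, 11.05, 4.30, -1.59),
    ("pancreas", "VTV"): (1.08, 1.08, 1.03, 1.07, 1.03, 1.06, 0.98, 1.00, 4.59, 3.90, -2.18),
    ("oligo", "GTV"): (1.51, 1.41, 1.44, 1.34, 1.33, 1.33, 1.29, 1.19, 10.35, 5.99, 5.48),
    ("oligo", "VTV"): (1.49, 1.39, 1.43, 1.32, 1.33, 1.31, 1.29, 1.18, 9.58, 5.45, 6.33),
    ("prostate", "GTV"): (1.41, 1.37, 1.35, 1.34, 1.07, 0.99, 1.03, 1.02, 28.41, 1.85, 3.09),
    ("prostate", "CTV"): (1.56, 1.52, 1.49, 1.46, 1.31, 1.29, 1.27, 1.29, 15.62, 3.00, 1.13),
}

#: Column-mean ("Mean value") row as printed, same column order.
PUBLISHED_MEAN_ROW = (1.32, 1.30, 1.26, 1.25, 1.09, 1.09, 1.05, 1.04, 18.27, 4.34, 0.36)


def consortium_table1() -> pd.DataFrame:
    """Full reference table: 8 condition-mean columns + 3 difference columns,
    indexed by (case, roi_type). Values in 10⁻³ mm²/s and percent."""
    table = pd.DataFrame.from_dict(_ROWS, orient="index")
    table.columns = CONDITION_ORDER + DIFFERENCE_COLUMNS
    table.index = pd.MultiIndex.from_tuples(table.index, names=["case", "roi_type"])
    return table


def consortium_condition_means() -> pd.DataFrame:
    """The 8 × 8 block of condition-mean ADCs (10⁻³ mm²/s)."""
    return consortium_table1()[CONDITION_ORDER]


def consortium_percent_differences() -> pd.DataFrame:
    """The 8 × 3 block of printed mean percent differences."""
    return consortium_table1()[DIFFERENCE_COLUMNS]
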