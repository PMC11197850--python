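"""Multi-centre reproducibility statistics for ADC values.

The central object is the cross-table of one clinical case and ROI type:
rows are the delineations contributed by each centre, columns the
calculation methods, and each cell the ADC obtained by applying that
method to that delineation. From it:

* CV_C — variation across calculation methods: the coefficient of
  variation (CV) of each row, averaged over rows.
* CV_D — variation across delineations: the CV of each column, averaged
  over columns.

CVs that are exactly zero (an artefact of coarse rounding in some local
software) are excluded from the averages and counted.

Repeatability uses the within-subject coefficient of variation (wCV) from
back-to-back test–retest acquisitions, the QIBA-recommended metric.
Differences between calculation conditions are tested with Friedman tests
(Bonferroni-corrected, m = 3 factors) and summarised as paired percent
differences with the pair mean as denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CrossTable",
    "CVSummary",
    "RepeatabilityResult",
    "ConditionTestResult",
    "coefficient_of_variation",
    "crosstable_cv",
    "within_subject_cv",
    "friedman_test",
    "bonferroni_adjust",
    "paired_percent_difference",
    "condition_comparison",
    "summarize_table1",
    "append_grand_mean",
    "expected_cell_count",
    "round_adc_table",
]

FACTOR_LEVELS = {
    "b_set": ("all", "b150"),  # all b-values minus b >= 150
    "mode": ("roi", "vox"),  # ROI-based minus voxel-based
    "statistic": ("mean", "median"),  # mean minus median
}


@dataclass
class CrossTable:
    """Delineation × calculation-method ADC matrix for one case/ROI type.

    ``values`` has delineating centres as the index and calculating
    centres/methods as columns, ADC in 10⁻³ mm²/s; NaN marks missing cells
    (omitted calculations), which are tracked, never imputed.
    """

    case_id: str
    roi_type: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("cross-table ADC values must be positive")

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def transpose(self) -> "CrossTable":
        return CrossTable(self.case_id, self.roi_type, self.values.T)


@dataclass
class CVSummary:
    """Cross-table variation summary.

    ``per_delineation_cv`` (one CV per row, across methods) averages to
    ``cv_c``; ``per_method_cv`` (one CV per column, across delineations)
    averages to ``cv_d``. Exact-zero CVs are excluded from both averages
    (``n_excluded_zero``); a mean with no surviving CVs is NaN.
    """

    cv_d: float
    cv_c: float
    per_method_cv: pd.Series
    per_delineation_cv: pd.Series
    n_excluded_zero: int
    n_skipped: int = 0


@dataclass
class RepeatabilityResult:
    wcv: float  # pooled, dimensionless
    per_case: pd.DataFrame  # case_id, y_test, y_retest, wcv


@dataclass
class ConditionTestResult:
    factor: str
    statistic: float
    p_raw: float
    p_adjusted: float
    mean_pct_difference: float
    n_blocks: int


def coefficient_of_variation(values: np.ndarray) -> float:
    """Sample CV: standard deviation (n−1 denominator) over the mean."""
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("CV requires a positive mean")
    return float(vals.std(ddof=1) / mean)


def _axis_cvs(values: pd.DataFrame, axis: int) -> tuple[pd.Series, int]:
    """CV along one axis, skipping (and counting) lines with <2 present values."""
    out, skipped = {}, 0
    items = values.iterrows() if axis == 1 else ((c, values[c]) for c in values.columns)
    for name, line in items:
        present = line.dropna()
        if len(present) < 2:
            skipped += 1
            continue
        out[name] = coefficient_of_variation(present.to_numpy())
    return pd.Series(out, dtype=float), skipped


def crosstable_cv(table: CrossTable) -> CVSummary:
    """CV_C (per-row mean) and CV_D (per-column mean) with zero-CV exclusion."""
    row_cvs, row_skipped = _axis_cvs(table.values, axis=1)
    col_cvs, col_skipped = _axis_cvs(table.values, axis=0)
    if row_cvs.empty and col_cvs.empty:
        raise ValueError("no usable rows or columns in the cross-table")

    def _mean_excluding_zero(cvs: pd.Series) -> tuple[float, int]:
        nonzero = cvs[cvs > 0]
        n_zero = int((cvs == 0).sum())
        return (float(nonzero.mean()) if len(nonzero) else float("nan")), n_zero

    cv_c, zeros_c = _mean_excluding_zero(row_cvs)
    cv_d, zeros_d = _mean_excluding_zero(col_cvs)
    n_skipped = row_skipped + col_skipped
    if n_skipped:
        logger.warning(
            "crosstable_cv (%s/%s): %d row(s)/column(s) skipped with <2 values",
            table.case_id, table.roi_type, n_skipped,
        )
    return CVSummary(
        cv_d=cv_d,
        cv_c=cv_c,
        per_method_cv=col_cvs,
        per_delineation_cv=row_cvs,
        n_excluded_zero=zeros_c + zeros_d,
        n_skipped=n_skipped,
    )


def within_subject_cv(
    pairs: list[tuple[float, float]], case_ids: list[str] | None = None
) -> RepeatabilityResult:
    """Test–retest repeatability.

    Per case, wCV_i = sqrt(d_i²/2) / ȳ_i with d_i the test−retest
    difference and ȳ_i the pair mean; the pooled value is the root mean of
    the per-case squared wCVs. Both are invariant to a common rescaling of
    the pair.
    """
    rows = []
    for i, (y1, y2) in enumerate(pairs):
        if y1 <= 0 or y2 <= 0:
            raise ValueError("test-retest values must be positive")
        mean = (y1 + y2) / 2.0
        wcv_i = float(np.sqrt((y1 - y2) ** 2 / 2.0) / mean)
        rows.append(
            {
                "case_id": case_ids[i] if case_ids else f"case_{i}",
                "y_test": y1,
                "y_retest": y2,
                "wcv": wcv_i,
            }
        )
    per_case = pd.DataFrame(rows)
    pooled = float(np.sqrt(np.mean(per_case["wcv"].to_numpy() ** 2)))
    return RepeatabilityResult(wcv=pooled, per_case=per_case)


def friedman_test(blocks: np.ndarray) -> tuple[float, float]:
    """Friedman rank test for k related treatments over n blocks.

    Values are ranked within each block (mid-ranks for ties) and the
    statistic is the rank-ANOVA form

        Q = n(k−1) · Σ_j (R̄_j − r̄)² / ( (1/n) Σ_ij (r_ij − r̄)² ),

    which reduces to 12n/(k(k+1))·Σ_j(R̄_j−(k+1)/2)² without ties and
    applies the standard tie correction with them. Blocks containing NaN
    are dropped. p from the χ²(k−1) approximation. Works for k = 2 (scipy's
    implementation requires k ≥ 3).
    """
    X = np.atleast_2d(np.asarray(blocks, dtype=float))
    X = X[~np.isnan(X).any(axis=1)]
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError(f"friedman_test needs >=2 blocks and >=2 treatments, got {X.shape}")
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    rbar = (k + 1) / 2.0
    col_means = ranks.mean(axis=0)
    ss_treat = n * np.sum((col_means - rbar) ** 2)
    ss_total = np.sum((ranks - rbar) ** 2) / n
    if ss_total <= 0:  # all values tied within every block
        return 0.0, 1.0
    q = n * (k - 1) * ss_treat / (n * ss_total)
    p = float(stats.chi2.sf(q, k - 1))
    return float(q), p


def bonferroni_adjust(p_values: list[float], m: int) -> list[float]:
    """Bonferroni correction: p → min(1, m·p)."""
    if m < len(p_values):
        raise ValueError("m must be >= number of p-values")
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
        out.append(min(1.0, m * p))
    return out


def paired_percent_difference(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Mean over pairs of 100·(a−b)/((a+b)/2).

    The pair mean is the denominator, so the measure is symmetric up to
    sign and invariant to a common rescaling.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("paired percent difference requires positive values")
    return float(np.mean(100.0 * (a - b) / ((a + b) / 2.0)))


def _require_columns(df: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"long table is missing columns: {missing}")


LONG_COLUMNS = [
    "case", "roi_type", "delineation_centre", "calc_centre",
    "b_set", "mode", "statistic", "adc",
]


def condition_comparison(
    study_results: pd.DataFrame, alpha: float = 0.05
) -> list[ConditionTestResult]:
    """Test each calculation factor (b-set, ROI/voxel, mean/median) on GTVs.

    Input is the long table of aligned-condition ADCs (columns
    ``LONG_COLUMNS``). For each factor, blocks are every (case ×
    delineation centre × calculating centre × other-factor combination)
    with both levels present; treatments are the factor's two levels.
    Friedman tests are Bonferroni-corrected for the 3 factors, and the
    paired percent difference (first level minus second) is reported.
    """
    _require_columns(study_results, LONG_COLUMNS)
    df = study_results[study_results["roi_type"] == "GTV"].dropna(subset=["adc"])
    if df.empty:
        raise ValueError("no GTV rows in the study results")
    results = []
    for factor, (lvl_a, lvl_b) in FACTOR_LEVELS.items():
        others = [f for f in FACTOR_LEVELS if f != factor]
        block_cols = ["case", "delineation_centre", "calc_centre"] + others
        wide = df.pivot_table(
            index=block_cols, columns=factor, values="adc", aggfunc="mean"
        )
        if lvl_a not in wide.columns or lvl_b not in wide.columns:
            raise ValueError(f"factor {factor}: missing level among {wide.columns.tolist()}")
        wide = wide[[lvl_a, lvl_b]].dropna()
        if len(wide) < 2:
            raise ValueError(f"factor {factor}: fewer than 2 complete blocks")
        q, p = friedman_test(wide.to_numpy())
        diff = paired_percent_difference(wide[lvl_a].to_numpy(), wide[lvl_b].to_numpy())
        results.append(
            ConditionTestResult(
                factor=factor,
                statistic=q,
                p_raw=p,
                p_adjusted=min(1.0, 3 * p),
                mean_pct_difference=diff,
                n_blocks=len(wide),
            )
        )
    return results


# Table-1-style summary -------------------------------------------------------

CONDITION_ORDER = [
    "all_roi_mean", "all_roi_median", "all_vox_mean", "all_vox_median",
    "b150_roi_mean", "b150_roi_median", "b150_vox_mean", "b150_vox_median",
]
DIFFERENCE_COLUMNS = ["pct_diff_b_set", "pct_diff_roi_vox", "pct_diff_mean_median"]


def _condition_label(row: pd.Series) -> str:
    return f"{row['b_set']}_{row['mode']}_{row['statistic']}"


def summarize_table1(study_results: pd.DataFrame, scale: float = 1e3) -> pd.DataFrame:
    """Condition-mean ADC table with percent-difference columns.

    One row per (case, ROI type): the mean ADC across all available
    (delineation × calculating centre) cells per pre-specified condition,
    in 10⁻³ mm²/s, followed by the three mean paired percent differences
    (paired at the finest level, then averaged). A final unweighted
    column-mean row ("Mean value") summarises the study.
    """
    _require_columns(study_results, LONG_COLUMNS)
    df = study_results.dropna(subset=["adc"]).copy()
    if df.empty:
        raise ValueError("empty study results")
    df["condition"] = df.apply(_condition_label, axis=1)
    df = df[df["condition"].isin(CONDITION_ORDER)]

    rows = {}
    for (case, roi), grp in df.groupby(["case", "roi_type"], sort=False):
        means = grp.groupby("condition")["adc"].mean() * scale
        row = {c: means.get(c, np.nan) for c in CONDITION_ORDER}
        pair_cols = ["delineation_centre", "calc_centre"]
        for col, factor in zip(
            DIFFERENCE_COLUMNS, ("b_set", "mode", "statistic")
        ):
            lvl_a, lvl_b = FACTOR_LEVELS[factor]
            others = [f for f in FACTOR_LEVELS if f != factor]
            wide = grp.pivot_table(
                index=pair_cols + others, columns=factor, values="adc", aggfunc="mean"
            )
            if lvl_a in wide.columns and lvl_b in wide.columns:
                wide = wide[[lvl_a, lvl_b]].dropna()
                row[col] = (
                    paired_percent_difference(wide[lvl_a], wide[lvl_b])
                    if len(wide)
                    else np.nan
                )
            else:
                row[col] = np.nan
        rows[(case, roi)] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["case", "roi_type"])
    return append_grand_mean(table)


def append_grand_mean(table: pd.DataFrame, label: str = "Mean value") -> pd.DataFrame:
    """Append the unweighted column-mean row across case/ROI rows."""
    if table.empty:
        raise ValueError("cannot summarise an empty table")
    grand = table.mean(axis=0)
    out = table.copy()
    if isinstance(out.index, pd.MultiIndex):
        out.loc[(label, ""), :] = grand
    else:
        out.loc[label] = grand
    return out


def round_adc_table(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Presentation rounding: ADC in 10⁻³ mm²/s at 2 decimals."""
    return table.round(decimals)


def expected_cell_count(n_delineations: int, n_centres: int, n_conditions: int) -> int:
    """Bookkeeping identity: expected ADC values = delineated volumes ×
    calculating centres × calculation-method combinations."""
    return int(n_delineations) * int(n_centres) * int(n_conditions)


def round_to_decimals(values: np.ndarray, decimals: int = 1) -> np.ndarray:
    """Emulate local software that reports ADC (10⁻³ mm²/s) at few decimals;
    coarse rounding is what produces exact-zero CVs in practice."""
    return np.round(np.asarray(values, dtype=float), decimals)
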