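"""Orchestration: simulate → fit → report, with config and provenance.

The pipeline realises the multi-centre study design: every calculating
centre evaluates every delineation under its own local method and under
the eight pre-specified calculation conditions. Aligned conditions fix the
b-subset, ROI/voxel mode and statistic, but each centre keeps its local
fit method and voxel filters — the residual "software implementation"
variation that alignment of conditions does not remove.

All outputs are plain CSV/JSON/Markdown and are byte-reproducible for a
fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adc_fitting import (
    PRESPECIFIED_CONDITIONS,
    BValueSet,
    CalcCondition,
    FitOptions,
    Mode,
    Statistic,
    aggregate_map,
    fit_voxel_map,
    roi_signal_fit,
)
from .contour_metrics import pairwise_contour_stats
from .dwi_data import DWISeries, load_dwi_series, load_mask, select_b_subset
from .reproducibility import (
    CrossTable,
    condition_comparison,
    crosstable_cv,
    expected_cell_count,
    round_adc_table,
    summarize_table1,
    within_subject_cv,
)
from .synthetic_data import (
    PhantomSpec,
    StudySpec,
    default_study_spec,
    expected_delineation_count,
    simulate_study,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "load_config",
    "run_simulate",
    "run_fit",
    "run_repeatability",
    "run_report",
    "run_all",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved pipeline configuration (YAML over defaults)."""

    seed: int = 0
    study_dir: str = "study"
    output_dir: str = "results"
    include_own_methods: bool = True
    noise_sigma: float = 2.0
    grid_shape: tuple[int, int, int] = (48, 48, 20)
    grid_spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)
    test_retest: bool = True
    repeatability_options: FitOptions = FitOptions(fit_method="wlls")

    def study_spec(self) -> StudySpec:
        spec = default_study_spec(seed=self.seed)
        base = replace(
            spec.base_phantom,
            shape=tuple(self.grid_shape),
            spacing=tuple(self.grid_spacing),
            noise_sigma=self.noise_sigma,
        )
        return replace(spec, base_phantom=base, test_retest=self.test_retest)

    def provenance(self) -> dict:
        payload = dataclasses.asdict(self)
        payload["repeatability_options"] = dataclasses.asdict(self.repeatability_options)
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()
        return {"config_hash": digest, "seed": self.seed, "version": __version__}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    kwargs = {}
    for fld in dataclasses.fields(PipelineConfig):
        if fld.name in data:
            value = data[fld.name]
            if fld.name in ("grid_shape", "grid_spacing"):
                value = tuple(value)
            if fld.name == "repeatability_options" and isinstance(value, dict):
                if "physical_range" in value:
                    value["physical_range"] = tuple(value["physical_range"])
                value = FitOptions(**value)
            kwargs[fld.name] = value
    unknown = set(data) - {f.name for f in dataclasses.fields(PipelineConfig)}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**kwargs)


def run_simulate(config: PipelineConfig) -> Path:
    """Generate the synthetic study and write provenance."""
    spec = config.study_spec()
    out = simulate_study(spec, config.study_dir)
    prov = config.provenance()
    prov["expected_delineations"] = expected_delineation_count(spec)
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
    logger.info(
        "simulated study: %d cases, %d centres, %d expected delineated volumes",
        len(spec.cases), len(spec.centres), prov["expected_delineations"],
    )
    return out


def _load_case_series(case_dir: Path, which: str = "test") -> DWISeries:
    return load_dwi_series(case_dir / f"dwi_{which}.nii.gz", case_dir / "dwi.bval")


def _condition_cells(
    centre, include_own: bool
) -> list[tuple[str, CalcCondition, FitOptions]]:
    cells = []
    if include_own:
        cells.append(("own", centre.own_condition, centre.own_fit_options))
    for cond in PRESPECIFIED_CONDITIONS:
        cells.append((cond.label, cond, centre.own_fit_options))
    return cells


def run_fit(config: PipelineConfig, study_dir: str | Path | None = None) -> pd.DataFrame:
    """Compute the full long-format ADC table.

    One row per (case, ROI, delineating centre, calculating centre,
    condition). Failures become missing cells with a reason, never aborts;
    the accounting identity computed + missing = expected is logged and
    stored in ``DataFrame.attrs``.
    """
    spec = config.study_spec()
    study = Path(study_dir if study_dir is not None else config.study_dir)
    manifest = pd.read_csv(study / "manifest.csv")
    n_conditions = len(PRESPECIFIED_CONDITIONS) + (1 if config.include_own_methods else 0)
    expected = expected_cell_count(len(manifest), len(spec.centres), n_conditions)

    rows = []
    for case_name, case_manifest in manifest.groupby("case", sort=False):
        series = _load_case_series(study / f"case_{case_name}")
        subsets = {"all": series}
        try:
            subsets["b150"] = select_b_subset(series, 150.0)
        except ValueError:
            pass
        for _, mrow in case_manifest.iterrows():
            mask = load_mask(
                study / mrow["path"], mrow["roi_type"], mrow["centre"],
                expected_shape=series.spatial_shape,
            )
            for centre in spec.centres:
                map_cache: dict[tuple[str, str], object] = {}
                for label, cond, opts in _condition_cells(centre, config.include_own_methods):
                    record = {
                        "case": case_name,
                        "roi_type": mrow["roi_type"],
                        "delineation_centre": mrow["centre"],
                        "calc_centre": centre.centre_id,
                        "method": label,
                        "b_set": cond.b_subset.value,
                        "mode": cond.mode.value,
                        "statistic": cond.statistic.value,
                        "adc": np.nan,
                        "reason": "",
                    }
                    try:
                        sub = subsets[cond.b_subset.value]
                        if cond.mode is Mode.ROI_BASED:
                            adc = roi_signal_fit(sub, mask, cond.statistic, opts).adc
                        else:
                            key = (cond.b_subset.value, opts.fit_method)
                            if key not in map_cache:
                                map_cache[key] = fit_voxel_map(sub, mask, opts)
                            adc = aggregate_map(map_cache[key], cond.statistic)
                        record["adc"] = adc
                    except (ValueError, KeyError) as exc:
                        record["reason"] = str(exc)
                    rows.append(record)
    table = pd.DataFrame(rows)
    n_missing = int(table["adc"].isna().sum())
    n_computed = len(table) - n_missing
    assert n_computed + n_missing == expected == len(table)
    table.attrs.update(
        {"expected_cells": expected, "computed_cells": n_computed, "missing_cells": n_missing}
    )
    logger.info(
        "ADC table: %d computed + %d missing = %d expected cells",
        n_computed, n_missing, expected,
    )
    return table


def run_repeatability(
    config: PipelineConfig, study_dir: str | Path | None = None
) -> pd.DataFrame:
    """Per-case test–retest median GTV ADC (voxel-based, b ≥ 150 s/mm²)."""
    study = Path(study_dir if study_dir is not None else config.study_dir)
    manifest = pd.read_csv(study / "manifest.csv")
    rows = []
    for case_name in manifest["case"].unique():
        case_dir = study / f"case_{case_name}"
        gtv_path = case_dir / "truth" / "gtv.nii.gz"
        values = {}
        for role in ("test", "retest"):
            series = select_b_subset(_load_case_series(case_dir, role), 150.0)
            mask = load_mask(gtv_path, "GTV", "truth", series.spatial_shape)
            adc_map = fit_voxel_map(series, mask, config.repeatability_options)
            values[role] = aggregate_map(adc_map, Statistic.MEDIAN)
        rows.append({"case": case_name, "y_test": values["test"], "y_retest": values["retest"]})
    return pd.DataFrame(rows)


def _build_crosstables(table: pd.DataFrame) -> dict[tuple[str, str, str], CrossTable]:
    """Cross-tables per (case, roi_type, method label); rows = delineating
    centre, columns = calculating centre. Non-positive fits become missing."""
    out = {}
    clean = table.copy()
    clean.loc[clean["adc"] <= 0, "adc"] = np.nan
    for (case, roi, label), grp in clean.groupby(
        ["case", "roi_type", "method"], sort=False
    ):
        wide = grp.pivot_table(
            index="delineation_centre", columns="calc_centre", values="adc"
        ).sort_index(axis=0).sort_index(axis=1)
        out[(case, roi, label)] = CrossTable(case, roi, wide * 1e3)
    return out


def run_report(
    config: PipelineConfig,
    table: pd.DataFrame,
    study_dir: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> Path:
    """Assemble the full report bundle from the long ADC table.

    Writes cross-tables, CV summaries per method (own + each aligned
    condition), pairwise contour statistics, test–retest wCV, the
    condition Friedman tests, and the Table-1-style summary.
    """
    if table.empty:
        raise ValueError("cannot report on an empty ADC table")
    study = Path(study_dir if study_dir is not None else config.study_dir)
    out = Path(out_dir if out_dir is not None else config.output_dir)
    (out / "crosstables").mkdir(parents=True, exist_ok=True)

    crosstables = _build_crosstables(table)
    cv_summary: dict = {}
    for (case, roi, label), xtab in sorted(crosstables.items()):
        xtab.values.to_csv(
            out / "crosstables" / f"{case}_{roi}_{label}.csv", float_format="%.6f"
        )
        try:
            cvs = crosstable_cv(xtab)
            entry = {
                "cv_d": None if np.isnan(cvs.cv_d) else round(cvs.cv_d, 6),
                "cv_c": None if np.isnan(cvs.cv_c) else round(cvs.cv_c, 6),
                "n_excluded_zero": cvs.n_excluded_zero,
            }
        except ValueError as exc:
            entry = {"cv_d": None, "cv_c": None, "error": str(exc)}
        cv_summary.setdefault(f"{case}/{roi}", {})[label] = entry
    (out / "cv_summary.json").write_text(
        json.dumps(cv_summary, indent=2, sort_keys=True) + "\n"
    )

    # contour agreement over each case/ROI's delineations
    manifest = pd.read_csv(study / "manifest.csv")
    contour_rows = []
    for (case, roi), grp in manifest.groupby(["case", "roi_type"], sort=False):
        masks = [
            load_mask(study / r["path"], roi, r["centre"]) for _, r in grp.iterrows()
        ]
        try:
            mean_dice, mean_msd, pairs = pairwise_contour_stats(masks)
        except ValueError:
            continue
        pairs.insert(0, "case", case)
        pairs.insert(1, "roi_type", roi)
        contour_rows.append(pairs)
    if contour_rows:
        pd.concat(contour_rows, ignore_index=True).to_csv(
            out / "contour_stats.csv", index=False, float_format="%.6f"
        )

    # repeatability
    if config.test_retest:
        pairs = run_repeatability(config, study)
        rep = within_subject_cv(
            list(zip(pairs["y_test"], pairs["y_retest"])), list(pairs["case"])
        )
        rep_payload = {
            "pooled_wcv_pct": round(100 * rep.wcv, 4),
            "per_case": [
                {
                    "case": r["case_id"],
                    "wcv_pct": round(100 * r["wcv"], 4),
                    "y_test_e3": round(1e3 * r["y_test"], 6),
                    "y_retest_e3": round(1e3 * r["y_retest"], 6),
                }
                for r in rep.per_case.to_dict("records")
            ],
        }
        (out / "repeatability.json").write_text(
            json.dumps(rep_payload, indent=2, sort_keys=True) + "\n"
        )

    # condition tests + Table-1-style summary on aligned conditions
    aligned = table[table["method"] != "own"]
    tests = condition_comparison(aligned)
    (out / "condition_tests.json").write_text(
        json.dumps(
            [dataclasses.asdict(t) for t in tests], indent=2, sort_keys=True
        )
        + "\n"
    )
    summary = round_adc_table(summarize_table1(aligned))
    summary.to_csv(out / "table1.csv", float_format="%.2f")

    _write_markdown_summary(out, config, table, cv_summary, tests)
    return out


def _write_markdown_summary(out: Path, config, table, cv_summary, tests) -> None:
    prov = config.provenance()
    lines = [
        "# ADC reproducibility report",
        "",
        f"- software version: {prov['version']}",
        f"- seed: {prov['seed']}, config hash: {prov['config_hash'][:12]}",
        f"- cells: {table.attrs.get('computed_cells', 'n/a')} computed + "
        f"{table.attrs.get('missing_cells', 'n/a')} missing = "
        f"{table.attrs.get('expected_cells', 'n/a')} expected",
        "",
        "## Condition tests (GTV, Friedman, Bonferroni m=3)",
        "",
    ]
    for t in tests:
        lines.append(
            f"- {t.factor}: mean diff {t.mean_pct_difference:+.2f}%, "
            f"Q={t.statistic:.2f}, p_adj={t.p_adjusted:.3g} (n={t.n_blocks} blocks)"
        )
    lines += ["", "## CV summaries", ""]
    for key in sorted(cv_summary):
        own = cv_summary[key].get("own", {})
        lines.append(f"- {key}: own-method CV_D={own.get('cv_d')}, CV_C={own.get('cv_c')}")
    (out / "summary.md").write_text("\n".join(lines) + "\n")


def run_all(config: PipelineConfig) -> Path:
    """simulate → fit → report with one config."""
    study = run_simulate(config)
    table = run_fit(config, study)
    out = run_report(config, table, study)
    table.to_csv(Path(out) / "adc_long.csv", index=False, float_format="%.10g")
    return out
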