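"""Mono-exponential ADC estimation under enumerated calculation conditions.

The signal model is the Stejskal–Tanner decay S(b) = S0·exp(−b·ADC), fitted
on the log scale: ln S is regressed on b, and ADC is minus the slope. Two
fit methods are provided:

* ``lls`` — ordinary least squares of ln S on b.
* ``wlls`` — weighted least squares with weights w_i = S_i². Under additive
  noise of constant variance on S, the variance of ln S is approximately
  σ²/S², so S² weighting is the first-order inverse-variance weighting;
  it down-weights the noisy high-b points.

A *calculation condition* is one cell of the 2×2×2 grid the consortium
pre-specified: b-subset (all b-values vs b ≥ 150 s/mm²) × ROI-based vs
voxel-based × mean vs median. ROI-based means the per-b mean (or median)
signal inside the ROI is computed first and one curve is fitted to those
aggregated signals; voxel-based means every voxel is fitted and the mean
(or median) of the per-voxel ADCs is taken. A ninth, centre-local method is
any condition plus a local :class:`FitOptions` override.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np

from .dwi_data import DWISeries, ROIMask, select_b_subset

__all__ = [
    "BValueSet",
    "Mode",
    "Statistic",
    "CalcCondition",
    "PRESPECIFIED_CONDITIONS",
    "B_GE_150_THRESHOLD",
    "FitOptions",
    "FitResult",
    "ADCMap",
    "log_linear_fit",
    "weighted_log_linear_fit",
    "fit_voxel_map",
    "roi_signal_fit",
    "aggregate_map",
    "compute_condition_adc",
    "save_adc_map",
]

B_GE_150_THRESHOLD = 150.0


class BValueSet(str, Enum):
    """Which acquired b-values enter the fit."""

    ALL = "all"
    B_GE_150 = "b150"


class Mode(str, Enum):
    ROI_BASED = "roi"
    VOXEL_BASED = "vox"


class Statistic(str, Enum):
    MEAN = "mean"
    MEDIAN = "median"


@dataclass(frozen=True)
class CalcCondition:
    """One cell of the pre-specified calculation-condition grid."""

    b_subset: BValueSet
    mode: Mode
    statistic: Statistic

    @property
    def label(self) -> str:
        return f"{self.b_subset.value}_{self.mode.value}_{self.statistic.value}"

    @property
    def min_b(self) -> float:
        return B_GE_150_THRESHOLD if self.b_subset is BValueSet.B_GE_150 else 0.0


#: The 8 pre-specified conditions, ordered as in the consortium report:
#: all-b before b≥150, ROI-based before voxel-based, mean before median.
PRESPECIFIED_CONDITIONS: tuple[CalcCondition, ...] = tuple(
    CalcCondition(b, m, s)
    for b, m, s in itertools.product(
        (BValueSet.ALL, BValueSet.B_GE_150),
        (Mode.ROI_BASED, Mode.VOXEL_BASED),
        (Statistic.MEAN, Statistic.MEDIAN),
    )
)


@dataclass(frozen=True)
class FitOptions:
    """Fit method and voxel-filtering choices.

    Parameters
    ----------
    fit_method : {"lls", "wlls"}
    physical_range : (lo, hi)
        Retained per-voxel ADC must lie in [lo, hi] mm²/s; the default
        upper bound 4×10⁻³ mm²/s exceeds free-water diffusivity at body
        temperature, so anything above it is non-physical.
    nonpositive_policy : {"drop_point", "drop_voxel"}
        Non-positive signals have no logarithm. ``drop_point`` removes the
        offending b-point from that voxel's fit (voxel dropped only if
        fewer than ``min_points`` remain); ``drop_voxel`` discards the
        whole voxel.
    min_points : int
        Minimum usable b-points per fit, ≥ 2.
    min_r_squared : float, optional
        Off by default. When set, voxel-based fits with more than two
        points and R² (on the ln S scale) below the threshold are excluded.
    min_snr, noise_sigma : float, optional
        Off by default. When both are set, voxels whose signal at the
        lowest fitted b-value is below ``min_snr * noise_sigma`` are
        excluded as low-SNR.
    """

    fit_method: str = "wlls"
    physical_range: tuple[float, float] = (0.0, 4.0e-3)
    nonpositive_policy: str = "drop_point"
    min_points: int = 2
    min_r_squared: float | None = None
    min_snr: float | None = None
    noise_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.fit_method not in ("lls", "wlls"):
            raise ValueError(f"unknown fit_method {self.fit_method!r}")
        if self.nonpositive_policy not in ("drop_point", "drop_voxel"):
            raise ValueError(f"unknown nonpositive_policy {self.nonpositive_policy!r}")
        lo, hi = self.physical_range
        if not lo < hi:
            raise ValueError("physical_range must satisfy lo < hi")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")


@dataclass(frozen=True)
class FitResult:
    """A single fitted decay: ADC (mm²/s), S0, R² (None for 2-point fits)."""

    adc: float
    s0: float
    r_squared: float | None
    n_points: int


# exclusion reasons for voxel maps
NONPHYSICAL = "nonphysical"
FIT_FAILED = "fit_failed"
LOW_SNR = "low_snr"
POOR_FIT = "poor_fit"


@dataclass
class ADCMap:
    """Per-voxel ADC values on the voxels of one ROI mask.

    ``values[i]`` is the ADC of mask voxel i (coordinates ``indices[i]``);
    ``excluded[i]`` is None for retained voxels or the exclusion reason.
    """

    shape: tuple[int, int, int]
    indices: np.ndarray  # (n_vox, 3) voxel coordinates
    values: np.ndarray  # (n_vox,) ADC in mm²/s, NaN where excluded
    excluded: np.ndarray  # (n_vox,) object: None or reason string
    condition_label: str = ""

    @property
    def retained(self) -> np.ndarray:
        return np.array([e is None for e in self.excluded])

    @property
    def n_used(self) -> int:
        return int(self.retained.sum())

    @property
    def n_excluded(self) -> int:
        return len(self.excluded) - self.n_used

    def retained_values(self) -> np.ndarray:
        return self.values[self.retained]

    def to_volume(self) -> np.ndarray:
        """Dense 3D float volume with NaN outside the mask / for excluded."""
        vol = np.full(self.shape, np.nan)
        keep = self.retained
        idx = self.indices[keep]
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] = self.values[keep]
        return vol


def _batch_log_fit(
    b_values: np.ndarray,
    signals: np.ndarray,
    fit_method: str,
    nonpositive_policy: str,
    min_points: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (weighted) log-linear fits for many voxels at once.

    Returns (adc, s0, r_squared, n_points, usable); r_squared is NaN for
    exactly-2-point fits and for unusable rows.
    """
    b = np.asarray(b_values, dtype=float)
    S = np.atleast_2d(np.asarray(signals, dtype=float))
    valid = S > 0
    if nonpositive_policy == "drop_voxel":
        all_ok = valid.all(axis=1)
        valid = valid & all_ok[:, None]

    w = np.where(valid, S**2 if fit_method == "wlls" else 1.0, 0.0)
    n_points = valid.sum(axis=1)
    y = np.where(valid, np.log(np.where(valid, S, 1.0)), 0.0)

    sw = w.sum(axis=1)
    swx = (w * b).sum(axis=1)
    swy = (w * y).sum(axis=1)
    swxx = (w * b * b).sum(axis=1)
    swxy = (w * b * y).sum(axis=1)
    denom = sw * swxx - swx**2

    # usable: enough points and at least two distinct weighted b-values
    b_scale = max(float(np.max(np.abs(b))), 1.0)
    usable = (n_points >= min_points) & (denom > 1e-12 * np.maximum(sw, 1e-300) ** 2 * b_scale**2)

    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(usable, (sw * swxy - swx * swy) / denom, np.nan)
        intercept = np.where(usable, (swxx * swy - swx * swxy) / denom, np.nan)
        yhat = intercept[:, None] + slope[:, None] * b[None, :]
        ss_res = (w * (y - yhat) ** 2).sum(axis=1)
        ybar = np.where(sw > 0, swy / np.maximum(sw, 1e-300), 0.0)
        ss_tot = (w * (y - ybar[:, None]) ** 2).sum(axis=1)
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0), 1.0)
    r2 = np.where(usable & (n_points > 2), r2, np.nan)
    adc = -slope
    s0 = np.exp(intercept)
    return adc, s0, r2, n_points, usable


def _single_fit(
    b_values: np.ndarray, signals: np.ndarray, fit_method: str, options: FitOptions
) -> FitResult:
    signals = np.asarray(signals, dtype=float).ravel()
    b = np.asarray(b_values, dtype=float).ravel()
    if b.size != signals.size:
        raise ValueError("b_values and signals must have equal length")
    adc, s0, r2, n, usable = _batch_log_fit(
        b, signals[None, :], fit_method, options.nonpositive_policy, options.min_points
    )
    if not usable[0]:
        raise ValueError(
            f"fit requires >= {options.min_points} positive signals at distinct "
            f"b-values; got {int(n[0])} usable point(s)"
        )
    r_squared = None if np.isnan(r2[0]) else float(r2[0])
    return FitResult(
        adc=float(adc[0]), s0=float(s0[0]), r_squared=r_squared, n_points=int(n[0])
    )


def log_linear_fit(
    b_values: np.ndarray, signals: np.ndarray, options: FitOptions = FitOptions()
) -> FitResult:
    """Ordinary least squares of ln S on b; ADC is minus the slope."""
    return _single_fit(b_values, signals, "lls", options)


def weighted_log_linear_fit(
    b_values: np.ndarray, signals: np.ndarray, options: FitOptions = FitOptions()
) -> FitResult:
    """Weighted least squares of ln S on b with weights S² (inverse variance
    of ln S under constant additive noise on the magnitude signal)."""
    return _single_fit(b_values, signals, "wlls", options)


def fit_voxel_map(
    series: DWISeries, mask: ROIMask, options: FitOptions = FitOptions()
) -> ADCMap:
    """Fit every mask voxel independently and apply the voxel filters.

    Unfittable voxels (too few positive points) are flagged ``fit_failed``;
    fitted ADCs outside ``physical_range`` are flagged ``nonphysical``;
    optional SNR and goodness-of-fit filters add ``low_snr`` / ``poor_fit``.
    Always: n_used + n_excluded == mask size.
    """
    if mask.is_empty:
        raise ValueError("cannot fit an empty mask")
    if mask.mask.shape != series.spatial_shape:
        raise ValueError(
            f"mask grid {mask.mask.shape} does not match DWI grid {series.spatial_shape}"
        )
    idx = np.argwhere(mask.mask)
    signals = series.signal[mask.mask, :]  # (n_vox, n_b)
    adc, s0, r2, n_points, usable = _batch_log_fit(
        series.b_values,
        signals,
        options.fit_method,
        options.nonpositive_policy,
        options.min_points,
    )

    excluded = np.full(len(idx), None, dtype=object)
    excluded[~usable] = FIT_FAILED
    lo, hi = options.physical_range
    bad_phys = usable & ((adc < lo) | (adc > hi))
    excluded[bad_phys] = NONPHYSICAL
    if options.min_snr is not None and options.noise_sigma is not None:
        low = signals[:, int(np.argmin(series.b_values))] < options.min_snr * options.noise_sigma
        excluded[(excluded == None) & low] = LOW_SNR  # noqa: E711
    if options.min_r_squared is not None:
        poor = usable & (n_points > 2) & (r2 < options.min_r_squared)
        excluded[(excluded == None) & poor] = POOR_FIT  # noqa: E711

    values = np.where(usable, adc, np.nan)
    return ADCMap(shape=series.spatial_shape, indices=idx, values=values, excluded=excluded)


def roi_signal_fit(
    series: DWISeries,
    mask: ROIMask,
    statistic: Statistic = Statistic.MEAN,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """ROI-based ADC: aggregate in-mask signal per b-value, then fit once."""
    if mask.is_empty:
        raise ValueError("cannot fit an empty mask")
    if mask.mask.shape != series.spatial_shape:
        raise ValueError("mask grid does not match DWI grid")
    signals = series.signal[mask.mask, :]
    agg = np.mean if Statistic(statistic) is Statistic.MEAN else np.median
    roi_signal = agg(signals, axis=0)
    return _single_fit(series.b_values, roi_signal, options.fit_method, options)


def aggregate_map(adc_map: ADCMap, statistic: Statistic = Statistic.MEAN) -> float:
    """Mean or median ADC over the retained voxels of a map.

    Median of an even count is the mean of the two central values.
    """
    vals = adc_map.retained_values()
    if vals.size == 0:
        raise ValueError("no retained voxels to aggregate")
    if Statistic(statistic) is Statistic.MEAN:
        return float(np.mean(vals))
    return float(np.median(vals))


def compute_condition_adc(
    series: DWISeries,
    mask: ROIMask,
    condition: CalcCondition,
    options: FitOptions = FitOptions(),
) -> float:
    """One cell of the study's ADC table: dispatch on the condition.

    Selects the b-subset, then either fits the aggregated ROI signal
    (ROI-based) or fits per voxel and aggregates the map (voxel-based).
    Deterministic for fixed inputs; failures raise and are recorded as
    missing cells by the pipeline, never imputed.
    """
    sub = select_b_subset(series, condition.min_b)
    if condition.mode is Mode.ROI_BASED:
        return roi_signal_fit(sub, mask, condition.statistic, options).adc
    adc_map = fit_voxel_map(sub, mask, options)
    return aggregate_map(adc_map, condition.statistic)


def save_adc_map(
    adc_map: ADCMap,
    path: str | Path,
    spacing: tuple[float, float, float],
    condition: CalcCondition | None = None,
    options: FitOptions | None = None,
    sidecar_path: str | Path | None = None,
) -> None:
    """Write an ADC map as float32 NIfTI (mm²/s, NaN = excluded) plus a JSON
    sidecar recording the condition, options and bookkeeping counts."""
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(adc_map.to_volume().astype(np.float32), affine)
    nib.save(img, str(path))
    if sidecar_path is None:
        sidecar_path = str(path).removesuffix(".gz").removesuffix(".nii") + ".json"
    from . import __version__

    meta = {
        "condition": condition.label if condition is not None else adc_map.condition_label,
        "options": None if options is None else {
            "fit_method": options.fit_method,
            "physical_range": list(options.physical_range),
            "nonpositive_policy": options.nonpositive_policy,
            "min_points": options.min_points,
        },
        "n_used": adc_map.n_used,
        "n_excluded": adc_map.n_excluded,
        "units": "mm^2/s",
        "software_version": __version__,
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
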