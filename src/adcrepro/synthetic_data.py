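"""Synthetic multi-centre DWI study generator with known ground truth.

No public patient data exist for the nine-centre MRI-linac ADC study
design, so this module emulates it end to end:

* four lesion "cases" (adrenal gland, pancreas, pelvic oligo metastasis,
  prostate analogues) as sphere-in-sphere phantoms with a viable shell and
  a necrotic core on a background tissue;
* signal from a biexponential intravoxel-incoherent-motion (IVIM) form
  S(b) = S0·[f·exp(−b·D*) + (1−f)·exp(−b·D)], so low b-values (< 100
  s/mm²) carry perfusion contamination that inflates a mono-exponential
  ADC fitted on all b-values;
* Rician magnitude noise, sqrt((S+n₁)² + n₂²), which produces the noise
  floor responsible for ADC underestimation at low SNR;
* nine simulated centres, each contributing one perturbed delineation per
  ROI (random rigid shift plus random dilation/erosion) and one distinct
  local calculation method (b-subset, statistic, fit method, filters);
* back-to-back test–retest acquisitions differing only in the noise
  realisation (no repositioning between scans).

All randomness fans out deterministically from one master seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .adc_fitting import BValueSet, CalcCondition, FitOptions, Mode, Statistic
from .dwi_data import DWISeries, ROIMask, save_dwi_series, save_mask

__all__ = [
    "PhantomTissue",
    "PhantomSpec",
    "CasePreset",
    "CentreSpec",
    "StudySpec",
    "ivim_signal",
    "build_phantom",
    "add_rician_noise",
    "perturb_delineation",
    "simulate_study",
    "default_study_spec",
    "default_case_presets",
    "default_centre_specs",
    "expected_delineation_count",
]


@dataclass(frozen=True)
class PhantomTissue:
    """Generative tissue parameters for the biexponential signal model."""

    s0: float  # baseline intensity, arbitrary units
    d: float  # true diffusion coefficient, mm²/s
    f: float = 0.0  # perfusion (pseudo-diffusion) signal fraction
    d_star: float = 50.0e-3  # pseudo-diffusion coefficient, mm²/s

    def __post_init__(self) -> None:
        if not (self.d_star > self.d >= 0):
            raise ValueError("requires d_star > d >= 0")
        if not (0 <= self.f < 1):
            raise ValueError("perfusion fraction must be in [0, 1)")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")


#: Default compartments: viable tumour, fluid-like necrotic core, background.
VIABLE = PhantomTissue(s0=100.0, d=1.1e-3, f=0.10)
NECROTIC = PhantomTissue(s0=130.0, d=2.5e-3, f=0.02)
BACKGROUND = PhantomTissue(s0=60.0, d=1.6e-3, f=0.08)

DEFAULT_B_LOW = (0.0, 30.0, 80.0, 150.0, 500.0)
DEFAULT_B_MID = (30.0, 80.0, 150.0, 300.0, 500.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Sphere-in-sphere lesion phantom.

    The gross tumour volume (GTV) is a sphere of ``r_lesion_mm``; the
    necrotic core a concentric sphere of ``r_core_mm``; the viable tumour
    volume (VTV) is GTV minus core, exactly.
    """

    shape: tuple[int, int, int] = (48, 48, 20)
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)
    r_lesion_mm: float = 12.0
    r_core_mm: float = 4.0
    viable: PhantomTissue = VIABLE
    necrotic: PhantomTissue = NECROTIC
    background: PhantomTissue = BACKGROUND
    b_values: tuple[float, ...] = DEFAULT_B_LOW
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.r_core_mm < self.r_lesion_mm:
            raise ValueError("core radius must be smaller than lesion radius")
        half_extent = min(
            n * s / 2.0 for n, s in zip(self.shape, self.spacing)
        )
        if self.r_lesion_mm >= half_extent:
            raise ValueError("lesion exceeds the grid")


def ivim_signal(b: float | np.ndarray, tissue: PhantomTissue) -> float | np.ndarray:
    """Biexponential IVIM signal S(b) = s0·[f·e^(−b·D*) + (1−f)·e^(−b·D)]."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    out = tissue.s0 * (
        tissue.f * np.exp(-b * tissue.d_star) + (1 - tissue.f) * np.exp(-b * tissue.d)
    )
    return float(out) if out.ndim == 0 else out


def _sphere_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    radius_mm: float,
    centre_mm: np.ndarray | None = None,
) -> np.ndarray:
    if radius_mm <= 0:
        return np.zeros(shape, dtype=bool)
    coords = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij")
    if centre_mm is None:
        centre_mm = np.array([(n - 1) * s / 2.0 for n, s in zip(shape, spacing)])
    r2 = sum((c - cm) ** 2 for c, cm in zip(coords, centre_mm))
    return r2 <= radius_mm**2


def build_phantom(spec: PhantomSpec) -> tuple[DWISeries, ROIMask, ROIMask]:
    """Noiseless phantom series plus the truth GTV and VTV masks."""
    gtv = _sphere_mask(spec.shape, spec.spacing, spec.r_lesion_mm)
    core = _sphere_mask(spec.shape, spec.spacing, spec.r_core_mm)
    vtv = gtv & ~core

    b = np.asarray(spec.b_values, dtype=float)
    signal = np.empty(spec.shape + (b.size,), dtype=float)
    signal[...] = ivim_signal(b, spec.background)[None, None, None, :]
    signal[vtv, :] = ivim_signal(b, spec.viable)
    signal[gtv & core, :] = ivim_signal(b, spec.necrotic)

    series = DWISeries(signal=signal, b_values=b, spacing=spec.spacing)
    gtv_mask = ROIMask(mask=gtv, roi_type="GTV", centre_id="truth", spacing=spec.spacing)
    vtv_mask = ROIMask(mask=vtv, roi_type="VTV", centre_id="truth", spacing=spec.spacing)
    return series, gtv_mask, vtv_mask


def add_rician_noise(
    series: DWISeries, sigma: float, seed: int | np.random.Generator = 0
) -> DWISeries:
    """Magnitude reconstruction of complex Gaussian noise:
    S → sqrt((S + n₁)² + n₂²), n₁, n₂ ~ N(0, σ²) i.i.d."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return series
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, series.signal.shape)
    n2 = rng.normal(0.0, sigma, series.signal.shape)
    noisy = np.sqrt((series.signal + n1) ** 2 + n2**2)
    return replace(series, signal=noisy)


def _integer_shift(mask: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Rigid integer-voxel translation with zero fill (no wrap-around)."""
    out = np.zeros_like(mask)
    src, dst = [], []
    for axis, k in enumerate(shift):
        n = mask.shape[axis]
        k = int(np.clip(k, -n + 1, n - 1))
        if k >= 0:
            src.append(slice(0, n - k))
            dst.append(slice(k, n))
        else:
            src.append(slice(-k, n))
            dst.append(slice(0, n + k))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def perturb_delineation(
    mask: ROIMask,
    shift_sigma_mm: float,
    morph_radius_voxels: int,
    seed: int | np.random.Generator = 0,
) -> ROIMask:
    """Emulate inter-observer delineation variability.

    A random rigid translation (per-axis Gaussian in mm, rounded to whole
    voxels) followed by a random dilation or erosion with a drawn radius
    up to ``morph_radius_voxels`` (6-connectivity). Erosion that would
    empty the mask is retried with a smaller radius, so the result is
    never empty. Deterministic per seed.
    """
    if mask.is_empty:
        raise ValueError("cannot perturb an empty delineation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shift_mm = rng.normal(0.0, shift_sigma_mm, 3)
    shift_vox = np.round(shift_mm / np.asarray(mask.spacing)).astype(int)
    out = _integer_shift(mask.mask, shift_vox)
    if not out.any():  # lesion shifted off-grid: fall back to the original
        out = mask.mask.copy()

    radius = int(rng.integers(0, morph_radius_voxels + 1))
    erode = bool(rng.integers(0, 2))
    structure = ndimage.generate_binary_structure(3, 1)
    if radius > 0:
        if erode:
            candidate = ndimage.binary_erosion(out, structure, iterations=radius)
            while not candidate.any() and radius > 1:
                radius -= 1
                candidate = ndimage.binary_erosion(out, structure, iterations=radius)
            if candidate.any():
                out = candidate
        else:
            out = ndimage.binary_dilation(out, structure, iterations=radius)
    return replace(mask, mask=out)


# Study-level specification ---------------------------------------------------


@dataclass(frozen=True)
class CasePreset:
    """One clinical-case analogue: lesion geometry, tissue, acquisition."""

    name: str
    r_lesion_mm: float
    r_core_mm: float
    d_viable: float  # mm²/s
    b_values: tuple[float, ...]
    delineation_scale: float = 1.0  # multiplies the centre shift sigma
    roi_types: tuple[str, ...] = ("GTV", "VTV")
    ctv_margin_mm: float = 4.0

    def phantom_spec(self, base: PhantomSpec) -> PhantomSpec:
        return replace(
            base,
            r_lesion_mm=self.r_lesion_mm,
            r_core_mm=self.r_core_mm,
            viable=replace(base.viable, d=self.d_viable),
            b_values=self.b_values,
        )


@dataclass(frozen=True)
class CentreSpec:
    """One simulated centre: delineation behaviour + local calculation method."""

    centre_id: str
    shift_sigma_mm: float = 1.5
    morph_radius_voxels: int = 1
    own_condition: CalcCondition = CalcCondition(
        BValueSet.B_GE_150, Mode.VOXEL_BASED, Statistic.MEDIAN
    )
    own_fit_options: FitOptions = FitOptions()


@dataclass(frozen=True)
class StudySpec:
    """The full multi-centre study design (defaults mirror the real one:
    9 centres, 4 cases, 8 delineated volumes, test–retest pairs)."""

    cases: tuple[CasePreset, ...]
    centres: tuple[CentreSpec, ...]
    base_phantom: PhantomSpec = PhantomSpec()
    seed: int = 0
    test_retest: bool = True


def default_case_presets() -> tuple[CasePreset, ...]:
    """Four case analogues.

    Sizes, diffusivities and perturbation scales are literature-plausible
    and qualitatively mirror the study's spread: the small pancreas lesion
    makes its VTV most sensitive to delineation, the prostate analogue has
    the largest delineation variation and uses a CTV instead of a VTV.
    Adrenal/pancreas use the (30…500) acquisition, oligo/prostate the
    (0…500) one.
    """
    return (
        CasePreset("adrenal", 12.0, 4.0, 1.1e-3, DEFAULT_B_MID, 1.0),
        CasePreset("pancreas", 7.0, 3.0, 1.3e-3, DEFAULT_B_MID, 1.6),
        CasePreset("oligo", 10.0, 4.0, 1.2e-3, DEFAULT_B_LOW, 0.8),
        CasePreset(
            "prostate", 16.0, 0.0, 0.9e-3, DEFAULT_B_LOW, 2.5, roi_types=("GTV", "CTV")
        ),
    )


def default_centre_specs() -> tuple[CentreSpec, ...]:
    """Nine centres with distinct local methods (all voxel-based, as in the
    real study), differing in b-subset, statistic, fit method and filters."""
    A, G = BValueSet.ALL, BValueSet.B_GE_150
    V = Mode.VOXEL_BASED
    ME, MD = Statistic.MEAN, Statistic.MEDIAN
    rows = [
        ("centre1", 1.2, 1, (A, V, MD), FitOptions("lls", (0.0, 4.0e-3))),
        ("centre2", 1.5, 1, (G, V, MD), FitOptions("wlls", (0.0, 3.0e-3))),
        ("centre3", 1.0, 0, (G, V, ME), FitOptions("lls", (0.0, 3.5e-3))),
        ("centre4", 1.8, 1, (A, V, ME), FitOptions("lls", (0.1e-3, 3.0e-3))),
        ("centre5", 1.4, 2, (G, V, MD), FitOptions("lls", (0.0, 4.0e-3), "drop_voxel")),
        ("centre6", 1.6, 1, (G, V, ME), FitOptions("wlls", (0.0, 4.0e-3))),
        ("centre7", 1.1, 1, (G, V, MD), FitOptions("wlls", (0.05e-3, 3.5e-3))),
        ("centre8", 1.3, 1, (A, V, MD), FitOptions("wlls", (0.0, 5.0e-3))),
        ("centre9", 1.7, 2, (G, V, ME), FitOptions("lls", (0.0, 4.0e-3))),
    ]
    return tuple(
        CentreSpec(cid, sig, mr, CalcCondition(*cond), opts)
        for cid, sig, mr, cond, opts in rows
    )


def default_study_spec(seed: int = 0) -> StudySpec:
    return StudySpec(
        cases=default_case_presets(),
        centres=default_centre_specs(),
        seed=seed,
    )


def expected_delineation_count(spec: StudySpec) -> int:
    """Expected delineated volumes: Σ_cases (ROI types) × centres."""
    return sum(len(c.roi_types) for c in spec.cases) * len(spec.centres)


def _child_seed(master: int, *tokens) -> int:
    """Deterministic per-component seed below 2^31, decoupled via hashing."""
    key = ":".join([str(master)] + [str(t) for t in tokens]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "little") % (2**31)


def _truth_masks(case: CasePreset, pspec: PhantomSpec) -> dict[str, ROIMask]:
    _, gtv, vtv = build_phantom(pspec)
    out: dict[str, ROIMask] = {}
    for roi in case.roi_types:
        if roi == "GTV":
            out[roi] = gtv
        elif roi == "VTV":
            out[roi] = vtv
        elif roi == "CTV":
            ctv = _sphere_mask(
                pspec.shape, pspec.spacing, case.r_lesion_mm + case.ctv_margin_mm
            )
            out[roi] = ROIMask(ctv, "CTV", "truth", pspec.spacing)
        else:
            raise ValueError(f"unknown ROI type {roi!r}")
    return out


def simulate_study(spec: StudySpec, out_dir: str | Path) -> Path:
    """Generate the full study on disk.

    Layout per case: ``case_<name>/dwi_noiseless.nii.gz``, ``dwi_test``,
    ``dwi_retest``, ``dwi.bval``, ``truth/<roitype>.nii.gz`` and
    ``masks/<centre>_<roitype>.nii.gz``; plus a study-level ``manifest.csv``
    (one row per delineated volume) and ``study.yaml`` with seed/config.
    Fixed master seed ⇒ byte-identical manifest and voxel-identical volumes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for case in spec.cases:
        pspec = case.phantom_spec(spec.base_phantom)
        case_dir = out / f"case_{case.name}"
        (case_dir / "masks").mkdir(parents=True, exist_ok=True)
        (case_dir / "truth").mkdir(exist_ok=True)

        series, _, _ = build_phantom(pspec)
        save_dwi_series(series, case_dir / "dwi_noiseless.nii.gz", case_dir / "dwi.bval")
        for role in ("test", "retest") if spec.test_retest else ("test",):
            noisy = add_rician_noise(
                series, pspec.noise_sigma, _child_seed(spec.seed, case.name, "noise", role)
            )
            save_dwi_series(noisy, case_dir / f"dwi_{role}.nii.gz")

        truths = _truth_masks(case, pspec)
        for roi, tmask in truths.items():
            save_mask(tmask, case_dir / "truth" / f"{roi.lower()}.nii.gz")

        for centre in spec.centres:
            for roi, tmask in truths.items():
                seed = _child_seed(spec.seed, case.name, centre.centre_id, "delin", roi)
                pert = perturb_delineation(
                    replace(tmask, centre_id=centre.centre_id),
                    centre.shift_sigma_mm * case.delineation_scale,
                    centre.morph_radius_voxels,
                    seed,
                )
                rel = f"case_{case.name}/masks/{centre.centre_id}_{roi.lower()}.nii.gz"
                save_mask(pert, out / rel)
                manifest_rows.append(
                    {
                        "case": case.name,
                        "centre": centre.centre_id,
                        "roi_type": roi,
                        "path": rel,
                        "n_voxels": pert.n_voxels,
                    }
                )

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    config = {
        "seed": spec.seed,
        "n_centres": len(spec.centres),
        "cases": [c.name for c in spec.cases],
        "expected_delineations": expected_delineation_count(spec),
        "b_values": {c.name: list(c.b_values) for c in spec.cases},
        "noise_sigma": spec.base_phantom.noise_sigma,
        "test_retest": spec.test_retest,
    }
    (out / "study.yaml").write_text(yaml.safe_dump(config, sort_keys=True))
    return out
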