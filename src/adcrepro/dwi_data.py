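"""Data model and I/O for diffusion-weighted MRI series and ROI masks.

A diffusion-weighted series is a stack of 3D magnitude volumes, one per
b-value (the diffusion-weighting strength in s/mm²). ADC fitting needs the
signal, the b-values, and the voxel spacing; everything else (orientation
matrices, acquisition metadata) is carried through but not interpreted.

b-value sidecars follow the FSL ``.bval`` dialect: whitespace-separated
numbers, one per volume, on one line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DWISeries",
    "ROIMask",
    "load_dwi_series",
    "save_dwi_series",
    "load_bvals",
    "save_bvals",
    "unscale_intensities",
    "select_b_subset",
    "load_mask",
    "save_mask",
]


@dataclass(frozen=True)
class DWISeries:
    """A 4D diffusion-weighted MRI acquisition.

    Parameters
    ----------
    signal : ndarray, shape (nx, ny, nz, nb)
        Magnitude signal, arbitrary units, non-negative.
    b_values : ndarray, shape (nb,)
        Diffusion weighting per volume, s/mm², non-negative.
    spacing : tuple of float
        Voxel edge lengths in mm per spatial axis, all positive.
    affine : ndarray, optional
        4×4 voxel-to-world matrix; stored for round-tripping only, all
        geometry uses ``spacing``.
    """

    signal: np.ndarray
    b_values: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        signal = np.asarray(self.signal, dtype=float)
        b_values = np.asarray(self.b_values, dtype=float).ravel()
        spacing = tuple(float(s) for s in self.spacing)
        if signal.ndim != 4:
            raise ValueError(f"signal must be 4D (x, y, z, b), got {signal.ndim}D")
        if signal.shape[3] != b_values.size:
            raise ValueError(
                f"{signal.shape[3]} volumes but {b_values.size} b-values"
            )
        if np.any(b_values < 0):
            raise ValueError("b-values must be non-negative")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        if np.any(signal < 0):
            raise ValueError("magnitude signal must be non-negative")
        object.__setattr__(self, "signal", signal)
        object.__setattr__(self, "b_values", b_values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def n_bvalues(self) -> int:
        return self.b_values.size

    def default_affine(self) -> np.ndarray:
        if self.affine is not None:
            return self.affine
        return np.diag(list(self.spacing) + [1.0])


@dataclass(frozen=True)
class ROIMask:
    """A binary region of interest on a DWI spatial grid.

    ``roi_type`` is one of the radiotherapy volumes: GTV (gross tumour
    volume), CTV (clinical target volume) or VTV (viable tumour volume,
    i.e. GTV minus cystic/necrotic parts). ``centre_id`` identifies the
    delineating centre.
    """

    mask: np.ndarray
    roi_type: str
    centre_id: str
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask).astype(bool)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got {mask.ndim}D")
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "spacing", spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()

    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing))


def load_bvals(path: str | Path) -> np.ndarray:
    """Read a plain-text b-value sidecar (whitespace-separated, one line)."""
    tokens = Path(path).read_text().split()
    if not tokens:
        raise ValueError(f"empty b-value sidecar: {path}")
    return np.array([float(t) for t in tokens])


def save_bvals(b_values: np.ndarray, path: str | Path) -> None:
    Path(path).write_text(" ".join(f"{b:g}" for b in np.asarray(b_values).ravel()) + "\n")


def load_dwi_series(
    image_path: str | Path,
    bval_path: str | Path,
    rescale: tuple[float, float] | None = None,
) -> DWISeries:
    """Load a 4D NIfTI plus its b-value sidecar.

    Parameters
    ----------
    rescale : (slope, intercept), optional
        Applied as ``true = slope * stored + intercept`` at load time
        (see :func:`unscale_intensities`).
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D DWI image, got {data.ndim}D: {image_path}")
    b_values = load_bvals(bval_path)
    if data.shape[3] != b_values.size:
        raise ValueError(
            f"{data.shape[3]} volumes in {image_path} but "
            f"{b_values.size} b-values in {bval_path}"
        )
    zooms = img.header.get_zooms()[:3]
    series = DWISeries(
        signal=data,
        b_values=b_values,
        spacing=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine),
    )
    if rescale is not None:
        series = unscale_intensities(series, *rescale)
    return series


def save_dwi_series(
    series: DWISeries, image_path: str | Path, bval_path: str | Path | None = None
) -> None:
    """Write a series as float32 NIfTI-1 plus an optional bval sidecar."""
    img = nib.Nifti1Image(series.signal.astype(np.float32), series.default_affine())
    img.header.set_zooms(tuple(series.spacing) + (1.0,))
    nib.save(img, str(image_path))
    if bval_path is not None:
        save_bvals(series.b_values, bval_path)


def unscale_intensities(series: DWISeries, slope: float, intercept: float) -> DWISeries:
    """Undo storage scaling: replace every stored value v by slope·v + intercept.

    DWI intensity histograms are often stretched to fill the storage bit
    depth; quantitative analysis needs the unscaled values. Negative results
    are clamped to zero (magnitude data) and the clamp count is logged.
    """
    if slope == 0:
        raise ValueError("rescale slope must be nonzero")
    values = slope * series.signal + intercept
    n_clamped = int(np.count_nonzero(values < 0))
    if n_clamped:
        logger.warning("unscale_intensities clamped %d negative voxels to 0", n_clamped)
        values = np.clip(values, 0.0, None)
    return replace(series, signal=values)


def select_b_subset(series: DWISeries, min_b: float) -> DWISeries:
    """Keep only volumes with b ≥ ``min_b``, preserving order.

    At least two volumes must survive, otherwise no exponential decay can
    be fitted.
    """
    keep = series.b_values >= min_b
    if keep.sum() < 2:
        raise ValueError(
            f"b >= {min_b} leaves {int(keep.sum())} volume(s); "
            "at least 2 are required for ADC fitting"
        )
    return replace(
        series, signal=series.signal[..., keep], b_values=series.b_values[keep]
    )


def load_mask(
    path: str | Path,
    roi_type: str,
    centre_id: str,
    expected_shape: tuple[int, int, int] | None = None,
) -> ROIMask:
    """Load a binary ROI mask (binarized at > 0.5) from a 3D NIfTI."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D mask, got {data.ndim}D: {path}")
    if expected_shape is not None and tuple(data.shape) != tuple(expected_shape):
        raise ValueError(
            f"mask grid {data.shape} does not match DWI grid {expected_shape}: {path}"
        )
    mask = data > 0.5
    if not mask.any():
        logger.warning("empty delineation loaded from %s (%s, %s)", path, roi_type, centre_id)
    zooms = img.header.get_zooms()[:3]
    return ROIMask(
        mask=mask,
        roi_type=roi_type,
        centre_id=centre_id,
        spacing=tuple(float(z) for z in zooms),
    )


def save_mask(roi: ROIMask, path: str | Path) -> None:
    affine = np.diag(list(roi.spacing) + [1.0])
    img = nib.Nifti1Image(roi.mask.astype(np.uint8), affine)
    img.header.set_zooms(tuple(roi.spacing))
    nib.save(img, str(path))
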