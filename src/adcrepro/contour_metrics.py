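"""Pairwise delineation agreement: Dice overlap and mean surface distance.

Dice = 2|A∩B| / (|A|+|B|) is dimensionless in [0, 1]. The mean surface
distance (MSD) is the symmetric average of the two directed mean
nearest-surface distances, in mm. Surfaces are voxel-centre based: a mask
voxel belongs to the surface iff it has a face-adjacent (6-connectivity)
background or out-of-grid neighbour; distances use the anisotropic voxel
spacing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .dwi_data import ROIMask

logger = logging.getLogger(__name__)

__all__ = [
    "ContourAgreement",
    "dice_coefficient",
    "extract_surface",
    "mean_surface_distance",
    "pairwise_contour_stats",
]


@dataclass(frozen=True)
class ContourAgreement:
    pair: tuple[str, str]
    dice: float
    msd: float


def _check_same_grid(a: ROIMask, b: ROIMask) -> None:
    if a.mask.shape != b.mask.shape:
        raise ValueError(f"grid mismatch: {a.mask.shape} vs {b.mask.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise ValueError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


def dice_coefficient(a: ROIMask, b: ROIMask) -> float:
    _check_same_grid(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise ValueError("Dice undefined for two empty masks")
    inter = int(np.count_nonzero(a.mask & b.mask))
    return 2.0 * inter / (na + nb)


def extract_surface(mask: ROIMask) -> np.ndarray:
    """Surface voxel centres in mm, shape (n_surface, 3).

    A voxel is on the surface iff any of its 6 face neighbours is
    background or lies outside the grid (erosion with background border).
    """
    if mask.is_empty:
        raise ValueError("cannot extract the surface of an empty mask")
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask.mask, structure=structure, border_value=0)
    surface = mask.mask & ~interior
    coords = np.argwhere(surface).astype(float)
    return coords * np.asarray(mask.spacing)


def mean_surface_distance(a: ROIMask, b: ROIMask) -> float:
    """Symmetric mean nearest-surface distance, mm:
    (mean_{p∈∂A} d(p, ∂B) + mean_{q∈∂B} d(q, ∂A)) / 2.
    """
    _check_same_grid(a, b)
    sa, sb = extract_surface(a), extract_surface(b)
    d_ab = cKDTree(sb).query(sa)[0].mean()
    d_ba = cKDTree(sa).query(sb)[0].mean()
    return float((d_ab + d_ba) / 2.0)


def pairwise_contour_stats(
    masks: list[ROIMask],
) -> tuple[float, float, pd.DataFrame]:
    """All unordered pairs of delineations → (mean Dice, mean MSD, table).

    Pairs with an empty member are skipped and counted in the table's
    attrs (mirrors missing-volume handling: no imputation). Means are
    unweighted over evaluated pairs.
    """
    usable = [m for m in masks if not m.is_empty]
    n_skipped_masks = len(masks) - len(usable)
    if len(usable) < 2:
        raise ValueError("need at least 2 non-empty masks for pairwise comparison")
    rows = []
    for a, b in itertools.combinations(usable, 2):
        rows.append(
            {
                "centre_a": a.centre_id,
                "centre_b": b.centre_id,
                "dice": dice_coefficient(a, b),
                "msd_mm": mean_surface_distance(a, b),
            }
        )
    table = pd.DataFrame(rows)
    n_skipped_pairs = len(masks) * (len(masks) - 1) // 2 - len(rows)
    if n_skipped_masks:
        logger.warning(
            "%d empty delineation(s) excluded from pairwise comparison", n_skipped_masks
        )
    table.attrs["n_skipped_pairs"] = n_skipped_pairs
    table.attrs["n_empty_masks"] = n_skipped_masks
    return float(table["dice"].mean()), float(table["msd_mm"].mean()), table
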