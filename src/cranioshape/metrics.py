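"""Segmentation-overlap and surface-distance metrics: DSC, border DSC, HD95.

Surfaces are the foreground voxels with at least one background face
neighbour (6-connectivity; voxels on the array border count as touching
background). Distances between surfaces are Euclidean in physical space,
using the voxel spacing, and are measured between voxel centers via an exact
Euclidean distance transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BinaryVolume

logger = logging.getLogger(__name__)


def surface_mask(data: np.ndarray) -> np.ndarray:
    """Boundary voxels: foreground with a background face-neighbour."""
    fg = data.astype(bool)
    face = ndimage.generate_binary_structure(3, 1)
    return fg & ~ndimage.binary_erosion(fg, structure=face, border_value=0)


def _directed_surface_distances(
    surf_from: np.ndarray, surf_to: np.ndarray, spacing
) -> np.ndarray:
    """Distance from every voxel of ``surf_from`` to the nearest of ``surf_to``."""
    dt = ndimage.distance_transform_edt(~surf_to, sampling=spacing)
    return dt[surf_from]


def dsc(a: BinaryVolume, b: BinaryVolume) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); two empty masks → 1."""
    a.require_same_grid(b)
    na, nb = a.foreground_count, b.foreground_count
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.data & b.data))
    return 2.0 * inter / (na + nb)


def border_dsc(a: BinaryVolume, b: BinaryVolume, tolerance_mm: float | None = None) -> float:
    """Surface Dice at a distance tolerance.

    A boundary voxel counts as matched when it lies within ``tolerance_mm``
    of the other mask's boundary; the score is (matched_A + matched_B) /
    (|∂A| + |∂B|). The default tolerance is one voxel's physical size
    (the largest spacing component).
    """
    a.require_same_grid(b)
    if tolerance_mm is None:
        tolerance_mm = float(max(a.spacing))
    sa, sb = surface_mask(a.data), surface_mask(b.data)
    na, nb = int(sa.sum()), int(sb.sum())
    if na + nb == 0:
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    d_ab = _directed_surface_distances(sa, sb, a.spacing)
    d_ba = _directed_surface_distances(sb, sa, a.spacing)
    matched = int((d_ab <= tolerance_mm).sum()) + int((d_ba <= tolerance_mm).sum())
    return matched / (na + nb)


def hd95(a: BinaryVolume, b: BinaryVolume) -> float:
    """95th percentile of the pooled directed surface distances (mm).

    The percentile is taken over the concatenation of the A→B and B→A
    distance sets (not the maximum of per-direction percentiles). An empty
    mask yields infinity with a warning; two empty masks compare as 0.
    """
    a.require_same_grid(b)
    sa, sb = surface_mask(a.data), surface_mask(b.data)
    if not sa.any() and not sb.any():
        return 0.0
    if not sa.any() or not sb.any():
        logger.warning("hd95 undefined against an empty mask; returning inf")
        return float("inf")
    d_ab = _directed_surface_distances(sa, sb, a.spacing)
    d_ba = _directed_surface_distances(sb, sa, a.spacing)
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


@dataclass(frozen=True)
class MetricsReport:
    """DSC, border DSC and HD95 of one mask pair."""

    dsc: float
    bdsc: float
    hd95: float
    tolerance_mm: float

    def to_dict(self) -> dict:
        return {
            "dsc": self.dsc, "bdsc": self.bdsc,
            "hd95": self.hd95, "tolerance_mm": self.tolerance_mm,
        }


def evaluate_pair(
    pred: BinaryVolume, reference: BinaryVolume, tolerance_mm: float | None = None
) -> MetricsReport:
    """All three metrics for a predicted mask against a reference mask."""
    tol = float(max(pred.spacing)) if tolerance_mm is None else float(tolerance_mm)
    return MetricsReport(
        dsc=dsc(pred, reference),
        bdsc=border_dsc(pred, reference, tolerance_mm=tol),
        hd95=hd95(pred, reference),
        tolerance_mm=tol,
    )
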