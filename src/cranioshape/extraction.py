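"""Automatic implant extraction from raw subtraction results.

Template subtraction leaves the true implant plus scattered residue wherever
template and subject disagree (facial region, interior structure, thin
misregistration shells). The clean-up pipeline is: median-based smoothing to
disconnect the implant from the noise, morphological opening with a cubic
structuring element to erase thin structures, then connected-component
analysis keeping the largest component(s). Cases where several comparably
sized components survive are flagged for manual review.

The smoothing step is a *hysteresis* median: a voxel survives if it lies
within one voxel of the median-stable core of the mask. A plain median filter
is strongly erosive on thin shell caps — it keeps shaving the implant rim on
every application — whereas the hysteresis variant removes isolated speckle
noise (no stable core nearby) while preserving rim voxels attached to solid
material. The whole pipeline is applied repeatedly until its output stops
changing (almost always one or two passes), which makes extraction
idempotent: re-extracting an extracted implant reproduces it exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BinaryVolume

logger = logging.getLogger(__name__)

_CONNECTIVITY_TO_RANK = {6: 1, 18: 2, 26: 3}
_MAX_PASSES = 10


@dataclass(frozen=True)
class ExtractionConfig:
    """Knobs of the smoothing → opening → component-selection pipeline.

    There is no universally good smoothing kernel — noisy, fragmented
    subtraction results need stronger smoothing than clean ones — so all
    stages are exposed. Defaults suit moderately noisy subtraction results on
    ~1 mm grids. ``keep`` is the number of components to retain: one per
    expected defect.
    """

    median_kernel: int = 3
    opening_radius: int = 1
    connectivity: int = 26
    min_component_volume: int = 1
    keep: int = 1
    ambiguity_ratio: float = 0.5  # QC: 2nd/1st component volume ratio that flags review

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError(f"median_kernel must be odd and >= 1, got {self.median_kernel}")
        if self.opening_radius < 0:
            raise ValueError(f"opening_radius must be >= 0, got {self.opening_radius}")
        if self.connectivity not in _CONNECTIVITY_TO_RANK:
            raise ValueError(f"connectivity must be one of {tuple(_CONNECTIVITY_TO_RANK)}")
        if self.keep < 1:
            raise ValueError(f"keep must be >= 1, got {self.keep}")


def hysteresis_median(data: np.ndarray, size: int = 3) -> np.ndarray:
    """Median-based despeckling that spares material attached to the core.

    Keeps exactly the input voxels lying within one voxel (26-neighbourhood)
    of the median-filtered mask. Isolated specks vanish; rims of thick
    structures survive. Always a subset of the input.
    """
    fg = data.astype(bool)
    if size <= 1:
        return fg
    core = ndimage.median_filter(fg.astype(np.uint8), size=size).astype(bool)
    return fg & ndimage.binary_dilation(core, structure=np.ones((3, 3, 3), bool))


def _label_sorted(data: np.ndarray, connectivity: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label components; return (labels, sizes, label order by size desc).

    Ties in volume are broken by the smallest linear C-order index of the
    component, for determinism.
    """
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_TO_RANK[connectivity])
    labels, n = ndimage.label(data, structure=structure)
    if n == 0:
        return labels, np.zeros(0, dtype=int), np.zeros(0, dtype=int)
    flat = labels.reshape(-1)
    sizes = np.bincount(flat)[1:]
    nz = np.flatnonzero(flat)
    lab_at_nz = flat[nz]
    order = np.argsort(lab_at_nz, kind="stable")
    uniq, starts = np.unique(lab_at_nz[order], return_index=True)
    first_index = np.empty(n, dtype=np.int64)
    first_index[uniq - 1] = nz[order][starts]
    rank = np.lexsort((first_index, -sizes))
    return labels, sizes, rank


def count_components(vol: BinaryVolume, connectivity: int = 26) -> tuple[int, np.ndarray]:
    """Number of connected components and their voxel volumes.

    Volumes are reported largest first; equal volumes are ordered by the
    smallest linear index of the component.
    """
    _, sizes, rank = _label_sorted(vol.data, connectivity)
    return int(sizes.shape[0]), sizes[rank]


def _one_pass(data: np.ndarray, config: ExtractionConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = hysteresis_median(data, size=config.median_kernel)
    if config.opening_radius > 0:
        # cubic block of side r+1: erases structures of local thickness <= r
        # while leaving anything at least r+1 thick (solids, shell caps) intact
        se = np.ones((config.opening_radius + 1,) * 3, dtype=bool)
        d = ndimage.binary_opening(d, structure=se)
    labels, sizes, rank = _label_sorted(d, config.connectivity)
    if sizes.size == 0:
        return np.zeros_like(d), sizes, rank
    selected = [lab + 1 for lab in rank[: config.keep]
                if sizes[lab] >= config.min_component_volume]
    if not selected:
        return np.zeros_like(d), sizes, rank
    return np.isin(labels, selected), sizes, rank


def extract_implant(
    raw: BinaryVolume, config: ExtractionConfig | None = None
) -> BinaryVolume:
    """Isolate the implant from a raw subtraction result.

    Pipeline (applied until stable): hysteresis median → binary opening
    (cubic structuring element of side radius+1, which erases structures of
    local thickness <= radius) → connected-component labeling → keep the
    ``config.keep`` largest components with at least
    ``config.min_component_volume`` voxels. The output only ever contains
    voxels that survive the smoothing of the input, and re-running the
    extraction on its own output reproduces it exactly.

    An empty result (everything filtered away) is returned as an empty volume
    with a logged warning — the signal that manual extraction is needed.
    """
    config = config or ExtractionConfig()
    data, first_sizes, first_rank = _one_pass(raw.data.astype(bool), config)
    for _ in range(_MAX_PASSES - 1):
        new, _, _ = _one_pass(data, config)
        if np.array_equal(new, data):
            break
        data = new
    if not data.any():
        logger.warning("implant extraction produced an empty volume; manual work needed")
        return BinaryVolume(np.zeros(raw.shape, np.uint8), raw.spacing, raw.origin)
    if first_sizes.size > config.keep:
        runner_up = first_sizes[first_rank[config.keep]]
        kept_smallest = first_sizes[first_rank[config.keep - 1]]
        if kept_smallest > 0 and runner_up / kept_smallest >= config.ambiguity_ratio:
            logger.warning(
                "ambiguous extraction: a discarded component (%d voxels) is "
                "comparable to the kept one (%d voxels); manual cleanup likely",
                runner_up, kept_smallest,
            )
    return BinaryVolume(data.astype(np.uint8), raw.spacing, raw.origin)
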