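"""Binary occupancy volumes with physical-grid metadata.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``data[x, y, z]``; axis ``k`` of the array corresponds to
  component ``k`` of ``spacing`` and ``origin``.
* Voxel indices are 0-based; the physical position of voxel ``(i, j, k)`` is
  ``origin + (i, j, k) * spacing`` (mm).
* Flattening a volume into a vector always uses C order (row-major) over the
  ``(x, y, z)`` index order above, so model coefficients stay aligned with
  voxels everywhere.
* Only axis-aligned volumes are supported: files whose direction/orientation
  matrix is not the identity are rejected rather than silently resampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import DimensionalityError, FormatError, GridMismatchError

logger = logging.getLogger(__name__)

_SUPPORTED_SUFFIXES = (".nrrd", ".nii", ".nii.gz")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a voxel grid: shape, spacing (mm/voxel) and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise DimensionalityError(f"grid must be 3D, got shape {self.shape}")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape components must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def to_sitk_reference(self) -> sitk.Image:
        """An empty SimpleITK image carrying this grid's geometry."""
        img = sitk.Image([int(s) for s in self.shape], sitk.sitkFloat32)
        img.SetSpacing([float(s) for s in self.spacing])
        img.SetOrigin([float(o) for o in self.origin])
        return img

    def matches(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class BinaryVolume:
    """A 3D binary voxel occupancy grid with spacing/origin metadata.

    ``data`` holds ``uint8`` values in {0, 1}; 1 marks anatomy (bone) and 0
    background. See the module docstring for the axis conventions.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"volume payload must be 3D, got {self.data.ndim}D"
            )
        uniq = np.unique(self.data)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("volume voxels must all be 0 or 1; binarize first")
        self.data = self.data.astype(np.uint8, copy=False)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.shape, self.spacing, self.origin)

    @property
    def foreground_count(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return self.foreground_count == 0

    def flatten(self) -> np.ndarray:
        """Row-major (C-order) flattening over the (x, y, z) index order."""
        return self.data.reshape(-1)

    def copy(self) -> "BinaryVolume":
        return BinaryVolume(self.data.copy(), self.spacing, self.origin)

    def same_grid(self, other: "BinaryVolume", tol: float = 1e-6) -> bool:
        return self.grid.matches(other.grid, tol=tol)

    def require_same_grid(self, other: "BinaryVolume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"volumes live on different grids: "
                f"{self.grid} vs {other.grid}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryVolume):
            return NotImplemented
        return self.same_grid(other) and np.array_equal(self.data, other.data)


def from_flat(vec: np.ndarray, grid: GridSpec, threshold: float = 0.5) -> BinaryVolume:
    """Reshape a flat (possibly real-valued) vector back onto ``grid``.

    Values >= ``threshold`` become foreground.
    """
    arr = np.asarray(vec).reshape(grid.shape)
    return BinaryVolume((arr >= threshold).astype(np.uint8), grid.spacing, grid.origin)


def to_sitk(vol: BinaryVolume, dtype=sitk.sitkUInt8) -> sitk.Image:
    """Convert to a SimpleITK image (which indexes arrays as (z, y, x))."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing([float(s) for s in vol.spacing])
    img.SetOrigin([float(o) for o in vol.origin])
    return sitk.Cast(img, dtype)


def from_sitk(img: sitk.Image, binarize_threshold: float = 0.5) -> BinaryVolume:
    """Convert a SimpleITK image into a BinaryVolume, thresholding values."""
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    data = (arr > binarize_threshold).astype(np.uint8)
    return BinaryVolume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not name.endswith(_SUPPORTED_SUFFIXES):
        raise FormatError(
            f"unsupported volume format for '{path}'; "
            f"expected one of {_SUPPORTED_SUFFIXES}"
        )


def _check_axis_aligned(img: sitk.Image, path: Path) -> None:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise FormatError(
            f"'{path}' has a non-axis-aligned direction matrix {direction.tolist()}; "
            "only axis-aligned segmentation masks are supported"
        )


def read_volume(path: str | Path, binarize_threshold: float = 0.5) -> BinaryVolume:
    """Read an NRRD or NIfTI segmentation mask as a BinaryVolume.

    Stored values strictly greater than ``binarize_threshold`` map to 1,
    everything else to 0. Spacing and origin come from the header; when the
    header carries none, SimpleITK's defaults of unit spacing and zero origin
    apply (a warning is logged).
    """
    path = Path(path)
    _check_suffix(path)
    if not path.exists():
        raise FormatError(f"volume file does not exist: '{path}'")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # sitk raises bare RuntimeError
        raise FormatError(f"could not read volume '{path}': {exc}") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"'{path}' holds a {img.GetDimension()}D payload; expected 3D"
        )
    _check_axis_aligned(img, path)
    keys = set(img.GetMetaDataKeys())
    if path.name.lower().endswith(".nrrd") and "NRRD_space" not in keys:
        logger.warning(
            "'%s' carries no spacing metadata; defaulting to unit spacing "
            "and zero origin",
            path,
        )
    if img.GetPixelID() != sitk.sitkFloat64:
        img = sitk.Cast(img, sitk.sitkFloat64)
    return from_sitk(img, binarize_threshold=binarize_threshold)


def write_volume(vol: BinaryVolume, path: str | Path) -> None:
    """Write a BinaryVolume as NRRD or NIfTI; round-trips through read_volume."""
    path = Path(path)
    _check_suffix(path)
    if not path.parent.exists():
        raise FormatError(f"parent directory does not exist: '{path.parent}'")
    try:
        sitk.WriteImage(to_sitk(vol), str(path), useCompression=True)
    except Exception as exc:
        raise FormatError(f"could not write volume '{path}': {exc}") from exc
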