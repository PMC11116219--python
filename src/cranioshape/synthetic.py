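"""Parametric skull-like phantoms and controlled synthetic defects.

The phantoms are hollow ellipsoidal shells — deliberately simple stand-ins
for binary skull segmentations. A cranium is a structurally simple, smooth,
roughly convex shell, so an ellipsoidal shell with inter-subject variation in
size, orientation, position and thickness exercises every stage of the
pipeline (registration, model building, completion, implant extraction)
without anatomical detail. An optional solid "facial lobe" appendage emulates
the cranium-versus-face imbalance of real skull masks.

Defects are carved out of a complete phantom so that the ground-truth implant
is known exactly: ``defective ∪ implant = complete`` and the two parts are
disjoint, voxel for voxel.

All randomness flows from explicit seeds; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import DegenerateInputError, PhantomSpecError
from .volume import BinaryVolume

DEFECT_KINDS = ("sphere", "cube", "multi_lobe", "border_crossing")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one hollow-shell phantom.

    Radii and thickness are in voxels; rotation is intrinsic x-y-z Euler
    angles in radians; translation displaces the shell center from the grid
    center, in voxels.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    radii: tuple[float, float, float] = (24.0, 20.0, 22.0)
    thickness: float = 4.0
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    facial_lobe: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.thickness < 1:
            raise PhantomSpecError(f"shell thickness must be >= 1 voxel, got {self.thickness}")
        if any(r <= self.thickness for r in self.radii):
            raise PhantomSpecError(
                f"all radii {self.radii} must exceed thickness {self.thickness}"
            )
        # conservative bound: rotated ellipsoid fits in a ball of max radius
        reach = max(self.radii) + np.abs(np.asarray(self.translation)).max()
        if reach >= min(self.grid_shape) / 2:
            raise PhantomSpecError(
                f"phantom (reach {reach:.1f} voxels) exceeds grid {self.grid_shape}"
            )


@dataclass(frozen=True)
class DefectSpec:
    """A synthetic defect carved from a complete shape.

    ``size_fraction`` is the target implant volume as a fraction of the
    complete shape's foreground; ``count`` > 1 places several disjoint lobes
    (each of size_fraction/count) to emulate skulls with multiple defects.
    """

    kind: str = "sphere"
    size_fraction: float = 0.2
    count: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in DEFECT_KINDS:
            raise PhantomSpecError(f"unknown defect kind '{self.kind}'; use one of {DEFECT_KINDS}")
        if not 0 < self.size_fraction < 0.5:
            raise PhantomSpecError(f"size_fraction must be in (0, 0.5), got {self.size_fraction}")
        if self.count < 1:
            raise PhantomSpecError(f"count must be >= 1, got {self.count}")


def generate_phantom(spec: PhantomSpec) -> BinaryVolume:
    """Render the hollow ellipsoidal shell described by ``spec``."""
    spec.validate()
    shape = spec.grid_shape
    idx = np.indices(shape, dtype=float)
    center = (np.asarray(shape, float) - 1) / 2 + np.asarray(spec.translation, float)
    R = Rotation.from_euler("xyz", spec.rotation).as_matrix()
    v = idx - center[:, None, None, None]
    u = np.einsum("ij,jxyz->ixyz", R.T, v)
    r_out = np.asarray(spec.radii, float)
    r_in = r_out - spec.thickness
    q_out = sum((u[k] / r_out[k]) ** 2 for k in range(3))
    q_in = sum((u[k] / r_in[k]) ** 2 for k in range(3))
    data = (q_out <= 1.0) & (q_in > 1.0)
    if spec.facial_lobe:
        # small solid ellipsoid attached at the front (+y), below the equator
        lobe_center = center + R @ np.array([0.0, 0.85 * r_out[1], -0.35 * r_out[2]])
        lv = idx - lobe_center[:, None, None, None]
        lu = np.einsum("ij,jxyz->ixyz", R.T, lv)
        lr = r_out / 3.0
        q_lobe = sum((lu[k] / lr[k]) ** 2 for k in range(3))
        data = data | (q_lobe <= 1.0)
    return BinaryVolume(data.astype(np.uint8), spec.spacing)


def analytic_shell_volume(spec: PhantomSpec) -> float:
    """Closed-form shell volume in voxels: 4/3 π (abc − a'b'c')."""
    r_out = np.asarray(spec.radii, float)
    r_in = r_out - spec.thickness
    return float(4.0 / 3.0 * np.pi * (np.prod(r_out) - np.prod(r_in)))


def _surface_candidates(complete: BinaryVolume, upper_only: bool = True) -> np.ndarray:
    """Voxel indices of outer-surface foreground, optionally upper half only."""
    data = complete.data.astype(bool)
    face = ndimage.generate_binary_structure(3, 1)
    surface = data & ~ndimage.binary_erosion(data, structure=face, border_value=0)
    idx = np.argwhere(surface)
    if upper_only:
        z_mid = np.argwhere(data)[:, 2].mean()
        upper = idx[idx[:, 2] >= z_mid]
        if upper.size:
            idx = upper
    return idx


def _region_mask(kind: str, center: np.ndarray, radius: float,
                 shape: tuple[int, int, int]) -> np.ndarray:
    coords = np.indices(shape, dtype=float)
    d = coords - center[:, None, None, None]
    if kind == "cube":
        return np.max(np.abs(d), axis=0) <= radius
    return np.sum(d * d, axis=0) <= radius * radius


def _fit_radius(kind: str, center: np.ndarray, complete: np.ndarray,
                target: int) -> np.ndarray:
    """Binary-search the region radius so the carved volume matches target."""
    lo, hi = 0.5, float(max(complete.shape))
    while _region_mask(kind, center, hi, complete.shape)[complete > 0].sum() < target \
            and hi < 4 * max(complete.shape):
        hi *= 1.5
    for _ in range(40):
        mid = (lo + hi) / 2
        vol = _region_mask(kind, center, mid, complete.shape)[complete > 0].sum()
        if vol < target:
            lo = mid
        else:
            hi = mid
    return _region_mask(kind, center, hi, complete.shape)


def apply_defect(complete: BinaryVolume, spec: DefectSpec) -> tuple[BinaryVolume, BinaryVolume]:
    """Carve ``spec`` out of a complete shape.

    Returns ``(defective, implant)`` with ``defective ∪ implant == complete``
    and ``defective ∩ implant == ∅`` exactly.
    """
    spec.validate()
    if complete.is_empty:
        raise DegenerateInputError("cannot apply a defect to an empty volume")
    rng = np.random.default_rng(spec.seed)
    data = complete.data.astype(bool)
    total = int(data.sum())
    candidates = _surface_candidates(complete)

    if spec.kind == "border_crossing":
        # center the defect on the shell voxel closest to a grid face, so the
        # carved region is clipped by the volume border
        dists_to_face = np.minimum(
            candidates, np.asarray(complete.shape) - 1 - candidates
        ).min(axis=1)
        centers = [candidates[int(np.argmin(dists_to_face))].astype(float)]
        n_lobes = 1
    elif spec.kind == "multi_lobe" or spec.count > 1:
        n_lobes = spec.count
        min_sep = 2.0 * (3 * spec.size_fraction / spec.count * total) ** (1 / 3)
        centers = []
        # relax the separation progressively if the shell is too small for it
        for factor in (1.0, 0.75, 0.5, 0.3):
            centers = []
            for _ in range(200):
                cand = candidates[rng.integers(len(candidates))].astype(float)
                if all(np.linalg.norm(cand - c) > factor * min_sep for c in centers):
                    centers.append(cand)
                if len(centers) == n_lobes:
                    break
            if len(centers) == n_lobes:
                break
        if len(centers) < n_lobes:
            raise PhantomSpecError(
                f"could not place {n_lobes} disjoint defect lobes on the shell"
            )
    else:
        n_lobes = 1
        centers = [candidates[rng.integers(len(candidates))].astype(float)]

    region_kind = "cube" if spec.kind == "cube" else "sphere"
    target_per_lobe = max(1, int(round(spec.size_fraction * total / n_lobes)))
    region = np.zeros(complete.shape, dtype=bool)
    for c in centers:
        region |= _fit_radius(region_kind, c, complete.data, target_per_lobe)

    implant_data = data & region
    if not implant_data.any():
        raise DegenerateInputError("defect region does not intersect the shape")
    defective_data = data & ~region
    implant = BinaryVolume(implant_data.astype(np.uint8), complete.spacing, complete.origin)
    defective = BinaryVolume(defective_data.astype(np.uint8), complete.spacing, complete.origin)
    return defective, implant


def sample_spec(base: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Draw one population member around ``base``.

    Variation ranges emulate moderate inter-subject differences: overall size
    within ±8% plus per-axis jitter of ±2%, shell thickness within ±8%,
    orientation within ~±10° and position within ±3 voxels. Overall size is
    recoverable by registration; the per-axis jitter and thickness spread are
    genuine (non-similarity) shape variation and bound how well two members
    can ever overlap — two shells of thickness t₁ < t₂ reach at best Dice
    2t₁/(t₁+t₂), so ±8% keeps ideally aligned members above ~0.92.
    """
    size = rng.uniform(0.92, 1.08)
    radii = tuple(np.asarray(base.radii) * size * rng.uniform(0.98, 1.02, size=3))
    thickness = float(base.thickness * rng.uniform(0.92, 1.08))
    rotation = tuple(rng.uniform(-0.18, 0.18, size=3))
    translation = tuple(rng.uniform(-3.0, 3.0, size=3))
    return replace(
        base, radii=radii, thickness=thickness,
        rotation=rotation, translation=translation,
    )


def generate_cohort(
    n: int, base_spec: PhantomSpec | None = None, seed: int = 0
) -> list[BinaryVolume]:
    """Generate ``n`` phantoms with sampled inter-subject variation."""
    if n < 2:
        raise PhantomSpecError(f"a cohort needs at least 2 members, got {n}")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    return [generate_phantom(sample_spec(base, rng)) for _ in range(n)]
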