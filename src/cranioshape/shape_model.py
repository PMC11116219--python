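"""Statistical shape model on voxel occupancy grids.

The model is built from a pool of complete shapes that have been registered
and warped into the grid of a designated reference member. With the warped,
flattened shapes stacked as rows of a matrix ``X'`` (C shapes × N voxels):

* the mean shape ``S̄`` is the voxelwise average of the rows;
* PCA of the rows (mean-centered) yields per-shape scores;
* the variation matrix ``Φ`` (d₀ × N) is the product of the score matrix with
  the Moore–Penrose pseudo-inverse of ``X'``, so that projecting a centered
  shape through ``Φ`` recovers its PCA scores;
* a new shape is reconstructed as ``S̄ + Σ_i λ_i Φ_i``, the weighted sum of
  variation modes added to the mean — algebraically identical to the
  inverse-PCA form ``S̄ + λ·Φ``.

Because C ≪ N, all heavy linear algebra happens on C×C or C×N matrices.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .errors import DegenerateInputError, GridMismatchError, PoolSizeError
from .registration import RegistrationConfig, register_similarity, warp
from .transforms import SimilarityTransform
from .volume import BinaryVolume, GridSpec, from_flat

logger = logging.getLogger(__name__)


@dataclass
class ShapePool:
    """A training set of complete shapes warped into a common reference grid.

    ``warped`` holds one flattened binary shape per row (C × N, float32,
    C-order flattening as documented in :mod:`cranioshape.volume`); the
    reference member's row is its own flattened data (identity transform).
    """

    members: list[BinaryVolume]
    reference_index: int
    warped: np.ndarray
    transforms: list[SimilarityTransform]
    grid: GridSpec

    @property
    def size(self) -> int:
        return self.warped.shape[0]

    @property
    def reference(self) -> BinaryVolume:
        return self.members[self.reference_index]

    @classmethod
    def from_matrix(cls, warped: np.ndarray, grid: GridSpec,
                    reference_index: int = 0) -> "ShapePool":
        """Build a pool directly from an already-warped row matrix.

        Intended for low-dimensional studies and tests; members are the
        re-shaped rows and all transforms are identity.
        """
        warped = np.asarray(warped, dtype=np.float32)
        if warped.ndim != 2 or warped.shape[1] != grid.n_voxels:
            raise GridMismatchError(
                f"warped matrix {warped.shape} does not match grid {grid.shape}"
            )
        members = [from_flat(row, grid) for row in warped]
        transforms = [SimilarityTransform.identity(grid) for _ in members]
        return cls(members, reference_index, warped, transforms, grid)


def choose_reference(volumes: list[BinaryVolume]) -> int:
    """Index of the member most representative of the pool.

    The reference's grid becomes the common space and its shape the
    registration target, so a member near the population median keeps every
    other member's residual mismatch small and symmetric. Representativeness
    is judged on two gross descriptors a similarity transform cannot change
    relative to the pool: overall size (cavity-filled volume) and relative
    wall thickness (foreground / filled ratio). The member with the smallest
    summed squared z-score wins.
    """
    if not volumes:
        raise PoolSizeError("cannot choose a reference from an empty list")
    from scipy import ndimage

    filled = np.array([
        int(ndimage.binary_fill_holes(v.data).sum()) for v in volumes
    ], dtype=float)
    shell = np.array([v.foreground_count for v in volumes], dtype=float)
    thickness_ratio = shell / np.maximum(filled, 1)

    def z(x: np.ndarray) -> np.ndarray:
        spread = x.std()
        return (x - np.median(x)) / spread if spread > 0 else np.zeros_like(x)

    score = z(filled) ** 2 + z(thickness_ratio) ** 2
    return int(np.argmin(score))


def build_pool(
    volumes: list[BinaryVolume],
    reference_index: int = 0,
    config: RegistrationConfig | None = None,
) -> ShapePool:
    """Register every member to the reference and stack the warped shapes.

    The reference member is copied through unchanged under an identity
    transform; every other member is registered to it with a similarity
    transform and resampled onto its grid.
    """
    if len(volumes) < 2:
        raise PoolSizeError(f"a shape pool needs >= 2 members, got {len(volumes)}")
    if not 0 <= reference_index < len(volumes):
        raise IndexError(f"reference_index {reference_index} out of range")
    for k, v in enumerate(volumes):
        if v.is_empty:
            raise DegenerateInputError(f"pool member {k} has empty foreground")

    reference = volumes[reference_index]
    grid = reference.grid
    rows, transforms = [], []
    for k, vol in enumerate(volumes):
        if k == reference_index:
            tr = SimilarityTransform.identity(grid)
            rows.append(vol.flatten().astype(np.float32))
        else:
            tr = register_similarity(vol, reference, config)
            rows.append(warp(vol, tr).flatten().astype(np.float32))
        transforms.append(tr)
    return ShapePool(list(volumes), reference_index, np.vstack(rows), transforms, grid)


def mean_shape(pool: ShapePool) -> np.ndarray:
    """Voxelwise average of the warped pool shapes; values lie in [0, 1]."""
    return pool.warped.mean(axis=0)


def mean_template(pool: ShapePool, subset_size: int | None = None,
                  threshold: float = 0.5) -> BinaryVolume:
    """Binarized mean over the first ``subset_size`` members — the S̄(n) template."""
    if subset_size is None:
        subset_size = pool.size
    if subset_size < 1:
        raise ValueError(f"subset_size must be >= 1, got {subset_size}")
    if subset_size > pool.size:
        raise ValueError(f"subset_size {subset_size} exceeds pool size {pool.size}")
    mean = pool.warped[:subset_size].mean(axis=0)
    return from_flat(mean, pool.grid, threshold=threshold)


@dataclass
class Weights:
    """Projection weights λ of a shape onto the variation modes."""

    lambda_raw: np.ndarray
    lambda_rescaled: np.ndarray

    def __post_init__(self) -> None:
        self.lambda_raw = np.asarray(self.lambda_raw, dtype=float).reshape(-1)
        self.lambda_rescaled = np.asarray(self.lambda_rescaled, dtype=float).reshape(-1)


def rescale_weights(lambda_raw: np.ndarray) -> np.ndarray:
    """Min–max rescaling of λ to [0, 1]; constant vectors map to zeros."""
    lam = np.asarray(lambda_raw, dtype=float)
    lo, hi = lam.min(), lam.max()
    if hi == lo:
        logger.warning("constant λ vector (max == min); rescaled weights set to 0")
        return np.zeros_like(lam)
    return (lam - lo) / (hi - lo)


@dataclass
class ShapeModel:
    """Mean shape, variation matrix and training scores of the SSM.

    ``variations`` has ``n_components`` rows of length N; ``scores`` is the
    (C × n_components) matrix of training-member PCA scores. The reference
    member's binary volume is kept so that new shapes can be registered into
    the model space.
    """

    mean: np.ndarray
    variations: np.ndarray
    scores: np.ndarray
    n_components: int
    grid: GridSpec
    reference_volume: BinaryVolume
    provenance: dict = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return self.scores.shape[0]


def fit_variations(pool: ShapePool, n_components: int | None = None) -> ShapeModel:
    """Fit the SSM: PCA scores of the warped rows, then Φ = scoresᵀ · pinv(X')ᵀ.

    ``pinv`` is the Moore–Penrose pseudo-inverse (SVD-based, singular values
    below 1e-10 × the largest treated as zero). A degenerate pool whose
    members are all identical yields zero variations with a warning.
    """
    C = pool.size
    if n_components is None:
        n_components = C
    if not 1 <= n_components <= C:
        raise ValueError(f"n_components must be in [1, {C}], got {n_components}")

    Xw = pool.warped.astype(np.float64)
    mean = Xw.mean(axis=0)
    if not np.any(Xw.std(axis=0) > 0):
        logger.warning("all pool members identical; variations set to zero")
        scores = np.zeros((C, n_components))
        variations = np.zeros((n_components, Xw.shape[1]))
    else:
        pca = PCA(n_components=n_components, svd_solver="full")
        scores = pca.fit_transform(Xw)
        pinv = np.linalg.pinv(Xw, rcond=1e-10)  # (N, C)
        variations = scores.T @ pinv.T

    return ShapeModel(
        mean=mean.astype(np.float32),
        variations=variations.astype(np.float32),
        scores=scores,
        n_components=n_components,
        grid=pool.grid,
        reference_volume=pool.reference.copy(),
        provenance={"n_members": C, "reference_index": pool.reference_index},
    )


def project(model: ShapeModel, warped_defective: np.ndarray) -> Weights:
    """Map a warped, flattened shape into the model's variation space.

    The input is mean-centered before applying Φ, matching the centering
    used when the scores were fitted, so that projecting a training member
    returns exactly its score row.
    """
    vec = np.asarray(warped_defective, dtype=np.float64).reshape(-1)
    if vec.shape[0] != model.grid.n_voxels:
        raise GridMismatchError(
            f"vector length {vec.shape[0]} does not match model grid "
            f"({model.grid.n_voxels} voxels)"
        )
    lam = model.variations.astype(np.float64) @ (vec - model.mean.astype(np.float64))
    return Weights(lambda_raw=lam, lambda_rescaled=rescale_weights(lam))


RECONSTRUCTION_MODES = ("eq_mean_plus_variations", "inverse_pca", "variations_only")


def reconstruct_field(
    model: ShapeModel, weights: Weights | np.ndarray,
    mode: str = "inverse_pca", use_rescaled: bool = False,
) -> np.ndarray:
    """Real-valued (pre-threshold) reconstruction from variation weights.

    Modes:

    * ``"eq_mean_plus_variations"`` — accumulate S̄ + Σ_i λ_i Φ_i mode by mode;
    * ``"inverse_pca"`` — the matrix form S̄ + λ·Φ (the inverse-PCA map);
    * ``"variations_only"`` — Σ_i λ_i Φ_i without the mean.

    The first two are algebraically identical and agree to float tolerance.
    """
    if mode not in RECONSTRUCTION_MODES:
        raise ValueError(f"unknown mode '{mode}'; use one of {RECONSTRUCTION_MODES}")
    if isinstance(weights, Weights):
        lam = weights.lambda_rescaled if use_rescaled else weights.lambda_raw
    else:
        lam = np.asarray(weights, dtype=float).reshape(-1)
    if lam.shape[0] != model.n_components:
        raise ValueError(
            f"weights length {lam.shape[0]} != n_components {model.n_components}"
        )
    Phi = model.variations.astype(np.float64)
    mean = model.mean.astype(np.float64)
    if mode == "eq_mean_plus_variations":
        out = mean.copy()
        for i in range(model.n_components):
            out += lam[i] * Phi[i]
        return out
    if mode == "inverse_pca":
        return mean + lam @ Phi
    return lam @ Phi


def reconstruct(
    model: ShapeModel, weights: Weights | np.ndarray,
    mode: str = "inverse_pca", threshold: float = 0.5, use_rescaled: bool = False,
) -> BinaryVolume:
    """Binarized reconstruction on the model's reference grid."""
    fieldv = reconstruct_field(model, weights, mode=mode, use_rescaled=use_rescaled)
    return from_flat(fieldv, model.grid, threshold=threshold)


def save_model(model: ShapeModel, path: str | Path) -> None:
    """Persist the model (arrays + geometry + provenance) as one .npz archive."""
    meta = {
        "n_components": model.n_components,
        "grid": {
            "shape": list(model.grid.shape),
            "spacing": list(model.grid.spacing),
            "origin": list(model.grid.origin),
        },
        "reference_grid": {
            "shape": list(model.reference_volume.shape),
            "spacing": list(model.reference_volume.spacing),
            "origin": list(model.reference_volume.origin),
        },
        "provenance": model.provenance,
    }
    np.savez_compressed(
        path,
        mean=model.mean,
        variations=model.variations,
        scores=model.scores,
        reference_data=np.packbits(model.reference_volume.data),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_model(path: str | Path) -> ShapeModel:
    with np.load(path) as npz:
        meta = json.loads(npz["meta"].tobytes().decode())
        g = meta["grid"]
        grid = GridSpec(tuple(g["shape"]), tuple(g["spacing"]), tuple(g["origin"]))
        rg = meta["reference_grid"]
        ref_shape = tuple(rg["shape"])
        n = int(np.prod(ref_shape))
        ref_data = np.unpackbits(npz["reference_data"])[:n].reshape(ref_shape)
        reference = BinaryVolume(ref_data, tuple(rg["spacing"]), tuple(rg["origin"]))
        return ShapeModel(
            mean=npz["mean"],
            variations=npz["variations"],
            scores=npz["scores"],
            n_components=int(meta["n_components"]),
            grid=grid,
            reference_volume=reference,
            provenance=meta.get("provenance", {}),
        )
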