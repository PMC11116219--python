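"""Shape completion: fill in the missing part of a defective skull.

Two routes, both operating in a common reference space:

* **Template subtraction** — register the defective shape to a complete
  template (a single reference skull or a binarized mean shape), subtract the
  warped defective shape from the template (clamped at zero on the binary
  grids), and take the remainder as the missing part.
* **SSM reconstruction** — register the defective shape into the model space,
  project it onto the variation modes, reconstruct a full skull from the mean
  shape plus weighted variations, and subtract as above.

Either way the completed shape is the disjoint union of the warped defective
shape and the derived missing part, and is carried back to the patient's
original grid by inverting the registration.

Pose refinement
---------------
A defective shape registered to a complete template with a symmetric metric
is systematically mis-posed: the metric drags template material into the
hole. Both routes therefore refine the pose by alternation, in the spirit of
active shape model fitting: after an initial completion, the defective shape
is re-registered against the current complete estimate (the subject-adapted
SSM reconstruction, or the template) with the estimated defect region —
dilated a few voxels — excluded from the metric, and the completion is
recomputed. A few iterations suffice; passing an explicit ``transform``
disables registration and refinement entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError
from .registration import (
    RegistrationConfig,
    register_affine_similarity,
    register_similarity,
    warp,
)
from .shape_model import ShapeModel, Weights, project, reconstruct_field
from .transforms import SimilarityTransform
from .volume import BinaryVolume, from_flat


@dataclass
class CompletionResult:
    """Everything a completion run produces, in both spaces.

    Invariants (checked at construction): the missing part and the warped
    defective shape are voxelwise disjoint, and the completed shape in the
    reference space is exactly their union.
    """

    defective_original: BinaryVolume
    warped_defective: BinaryVolume
    missing_part: BinaryVolume
    completed_reference: BinaryVolume
    completed_original: BinaryVolume
    transform: SimilarityTransform
    method: str  # "template" | "ssm"
    template_id: str

    def __post_init__(self) -> None:
        ym, yp = self.missing_part.data, self.warped_defective.data
        if np.any(ym & yp):
            raise AssertionError("missing part overlaps the warped defective shape")
        if not np.array_equal(self.completed_reference.data, ym | yp):
            raise AssertionError("completed shape is not the union of its parts")

    @property
    def implant_raw_original(self) -> BinaryVolume:
        """Raw implant estimate on the original grid: completed minus input."""
        data = self.completed_original.data & ~self.defective_original.data
        return BinaryVolume(
            data, self.defective_original.spacing, self.defective_original.origin
        )


def _denoise_missing(missing: np.ndarray, min_fraction: float) -> np.ndarray:
    """Drop disconnected specks of 'missing' material.

    Subtraction leaves, besides the defect fill, a sprinkling of tiny
    disconnected components wherever the complete estimate protrudes a voxel
    past the warped defective shell — misregistration dust, not anatomy.
    Components smaller than ``min_fraction`` of the largest are discarded
    (26-connectivity). Genuine fills are orders of magnitude larger, and a
    clean subtraction (exact pose) passes through untouched.
    """
    if min_fraction <= 0 or not missing.any():
        return missing
    structure = ndimage.generate_binary_structure(3, 3)
    labels, n = ndimage.label(missing, structure=structure)
    if n <= 1:
        return missing
    sizes = np.bincount(labels.reshape(-1))[1:]
    keep = np.flatnonzero(sizes >= min_fraction * sizes.max()) + 1
    return np.isin(labels, keep).astype(missing.dtype)


def _assemble(
    defective: BinaryVolume,
    tr: SimilarityTransform,
    warped_defective: BinaryVolume,
    full_shape: np.ndarray,
    method: str,
    template_id: str,
    min_missing_fraction: float = 0.02,
) -> CompletionResult:
    """Subtract, unite and warp back; shared tail of both completion routes."""
    missing_data = (full_shape & ~warped_defective.data).astype(np.uint8)
    missing_data = _denoise_missing(missing_data, min_missing_fraction)
    completed_ref_data = (missing_data | warped_defective.data).astype(np.uint8)
    grid = tr.target_grid
    missing = BinaryVolume(missing_data, grid.spacing, grid.origin)
    completed_ref = BinaryVolume(completed_ref_data, grid.spacing, grid.origin)
    inverse = tr.invert(defective.grid)
    completed_orig = warp(completed_ref, inverse)
    # the subject's own (unwarped) voxels are authoritative in original space
    completed_orig = BinaryVolume(
        completed_orig.data | defective.data, defective.spacing, defective.origin
    )
    return CompletionResult(
        defective_original=defective,
        warped_defective=warped_defective,
        missing_part=missing,
        completed_reference=completed_ref,
        completed_original=completed_orig,
        transform=tr,
        method=method,
        template_id=template_id,
    )


def _is_near_complete(result: CompletionResult, threshold: float) -> bool:
    """True when the input shape is effectively already complete.

    Pose refinement exists to counter hole-induced registration bias; when
    the initial completion finds (almost) nothing missing there is no hole,
    no bias, and nothing for refinement to correct — re-registering would
    only perturb an already-correct pose.
    """
    observed = result.defective_original.foreground_count
    return result.missing_part.foreground_count < threshold * max(1, observed)


def _dilated(mask: BinaryVolume, iterations: int) -> BinaryVolume:
    data = ndimage.binary_dilation(mask.data, iterations=iterations).astype(np.uint8) \
        if iterations > 0 else mask.data
    return BinaryVolume(data, mask.spacing, mask.origin)


def complete_by_template(
    defective: BinaryVolume,
    template: BinaryVolume,
    config: RegistrationConfig | None = None,
    transform: SimilarityTransform | None = None,
    template_id: str = "template",
    refine_iterations: int = 3,
    exclusion_dilation: int = 3,
    min_missing_fraction: float = 0.02,
    refine_skip_missing_fraction: float = 0.03,
) -> CompletionResult:
    """Template-subtraction completion.

    The defective shape is registered to the complete ``template``, the
    missing part is the clamped subtraction template − warped defective, and
    the completed shape is their union, warped back to the original grid. The
    pose is then refined ``refine_iterations`` times by re-registering with
    the estimated missing region excluded from the metric (see the module
    docstring). Pass ``transform`` to reuse a precomputed registration; this
    skips refinement.
    """
    if defective.is_empty or template.is_empty:
        raise DegenerateInputError("defective shape and template must be non-empty")
    config = config or RegistrationConfig()
    tr = transform if transform is not None else register_similarity(
        defective, template, config
    )
    result = _assemble(
        defective, tr, warp(defective, tr), template.data.astype(np.uint8),
        method="template", template_id=template_id,
        min_missing_fraction=min_missing_fraction,
    )
    if transform is not None or _is_near_complete(result, refine_skip_missing_fraction):
        return result
    refine_config = RegistrationConfig(levels=config.levels, ftol=config.ftol,
                                       rotation_regularization=0.01)
    for _ in range(refine_iterations):
        tr = register_affine_similarity(
            defective, template, refine_config,
            exclude=_dilated(result.missing_part, exclusion_dilation),
            initial_transform=result.transform,
        )
        result = _assemble(
            defective, tr, warp(defective, tr), template.data.astype(np.uint8),
            method="template", template_id=template_id,
            min_missing_fraction=min_missing_fraction,
        )
    return result


def complete_by_ssm(
    defective: BinaryVolume,
    model: ShapeModel,
    config: RegistrationConfig | None = None,
    transform: SimilarityTransform | None = None,
    threshold: float = 0.5,
    use_rescaled: bool = False,
    refine_iterations: int = 3,
    exclusion_dilation: int = 3,
    min_missing_fraction: float = 0.02,
    refine_skip_missing_fraction: float = 0.03,
) -> tuple[CompletionResult, Weights]:
    """SSM completion: register, project, reconstruct, subtract, warp back.

    The whole skull is reconstructed from the model (mean + weighted
    variations, binarized at ``threshold``) and the missing part derived by
    subtraction — the implant is never reconstructed directly. The pose is
    refined by re-registering the defective shape against the subject-adapted
    reconstruction with the estimated defect excluded (see module docstring).
    By default the raw projection weights feed the reconstruction (the exact
    PCA-inverse path); set ``use_rescaled`` for min–max-rescaled weights.
    Pass ``transform`` to reuse a precomputed registration; this skips
    refinement.
    """
    if defective.is_empty:
        raise DegenerateInputError("defective shape must be non-empty")
    config = config or RegistrationConfig()

    def run(tr: SimilarityTransform) -> tuple[CompletionResult, Weights, BinaryVolume]:
        warped_defective = warp(defective, tr)
        weights = project(model, warped_defective.flatten())
        fieldv = reconstruct_field(
            model, weights, mode="inverse_pca", use_rescaled=use_rescaled
        )
        full = from_flat(fieldv, model.grid, threshold=threshold)
        res = _assemble(
            defective, tr, warped_defective, full.data,
            method="ssm", template_id=f"ssm({model.n_members})",
            min_missing_fraction=min_missing_fraction,
        )
        return res, weights, full

    tr = transform if transform is not None else register_similarity(
        defective, model.reference_volume, config
    )
    result, weights, recon = run(tr)
    if transform is not None or _is_near_complete(result, refine_skip_missing_fraction):
        return result, weights
    refine_config = RegistrationConfig(levels=config.levels, ftol=config.ftol,
                                       rotation_regularization=0.01)
    for _ in range(refine_iterations):
        if recon.is_empty:
            break
        tr = register_affine_similarity(
            defective, recon, refine_config,
            exclude=_dilated(result.missing_part, exclusion_dilation),
            initial_transform=result.transform,
        )
        result, weights, recon = run(tr)
    return result, weights
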