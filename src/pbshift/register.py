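"""Skull-restricted affine alignment and elastic PBS-field extraction.

The two deformation states of one head are first aligned rigid-body-wise
using the skull alone — the skull is rigid, so restricting the affine
similarity to a (dilated) skull mask removes the bias that brain-shift
motion would otherwise leak into the global alignment. The aligned pair
is then registered elastically with a multi-resolution cubic B-spline
free-form deformation driven by masked normalized cross-correlation; the
resulting dense warp field is the positional-brain-shift displacement
field alone.

The numerical machinery is SimpleITK's ``ImageRegistrationMethod``;
this module owns the geometry conventions (RAS world frames, fields in
world mm on the fixed grid) and the evaluation statistics.

Conventions
-----------
* :class:`AffineTransform.matrix` maps moving-world → fixed-world (RAS
  mm); its ``rotation`` is the polar-decomposition rotation part.
* The elastic output ``u`` lives on the fixed grid with
  ``moving(x + u(x)) ≈ fixed(x)`` — for a pair generated by
  :func:`pbshift.synthcohort.warp_volume` the ground truth of ``u`` is
  exactly the generating field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .normalize import polar_rotation
from .volio import DisplacementField, ImageVolume, MaskVolume

_D = np.diag([-1.0, -1.0, 1.0])  # RAS <-> LPS component flip


# ---------------------------------------------------------------------------
# RAS <-> SimpleITK (LPS) plumbing


def _to_sitk(data: np.ndarray, affine: np.ndarray, dtype=np.float64) -> sitk.Image:
    a3 = affine[:3, :3]
    sp = np.linalg.norm(a3, axis=0)
    direction = _D @ (a3 / sp)
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(data, (2, 1, 0))).astype(dtype)
    )
    img.SetSpacing(tuple(sp))
    img.SetDirection(tuple(direction.flatten()))
    img.SetOrigin(tuple(_D @ affine[:3, 3]))
    return img


def _mask_to_sitk(mask: np.ndarray, affine: np.ndarray) -> sitk.Image:
    return sitk.Cast(_to_sitk(mask.astype(np.float64), affine), sitk.sitkUInt8)


def _lps_affine_to_ras(tx: sitk.Transform) -> np.ndarray:
    """4×4 RAS world map of an (affine-reducible) sitk transform
    (which maps fixed physical points to moving physical points)."""
    # flatten by the transform's action on the origin and basis points
    # (exact for any affine-acting transform, incl. Euler and composite)
    origin = np.asarray(tx.TransformPoint((0.0, 0.0, 0.0)))
    lin = np.zeros((3, 3))
    for i in range(3):
        e = np.zeros(3)
        e[i] = 1.0
        lin[:, i] = np.asarray(tx.TransformPoint(tuple(e))) - origin
    out = np.eye(4)
    out[:3, :3] = _D @ lin @ _D
    out[:3, 3] = _D @ origin
    return out


def _dense_field(tx: sitk.Transform, ref: sitk.Image) -> np.ndarray:
    f = sitk.TransformToDisplacementFieldFilter()
    f.SetReferenceImage(ref)
    arr = sitk.GetArrayFromImage(f.Execute(tx))  # (z, y, x, 3) LPS mm
    return np.transpose(arr, (2, 1, 0, 3)) @ _D.T  # -> (x, y, z, 3) RAS


# ---------------------------------------------------------------------------
# public types


@dataclass(frozen=True)
class AffineTransform:
    """World→world affine (RAS mm), moving → fixed."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4) or abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("matrix must be an invertible 4x4 affine")
        object.__setattr__(self, "matrix", m)

    @property
    def rotation(self) -> np.ndarray:
        """Proper-orthogonal rotation part (polar decomposition)."""
        return polar_rotation(self.matrix[:3, :3])

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))


@dataclass(frozen=True)
class RegistrationReport:
    """Endpoint-error statistics over the brain mask, in mm."""

    mean: float
    sd: float
    p5: float
    p95: float
    n_voxels: int
    folding_detected: bool = False
    convergence: tuple = ()

    def __post_init__(self):
        if not (0 <= self.p5 <= self.p95):
            raise ValueError("percentiles out of order")


@dataclass(frozen=True)
class RegistrationParams:
    """Elastic-registration settings.

    ``mesh_size`` is the coarsest-level B-spline control mesh (cells per
    axis); each additional entry of ``scale_factors`` doubles the mesh
    density, so the finest control spacing is
    ``image extent / (mesh_size * scale_factors[-1])``. ``similarity``
    is ``"ncc"`` (normalized cross-correlation over the masked region,
    default), ``"lncc"`` (local NCC with ``lncc_radius`` voxels) or
    ``"mse"``.
    """

    mesh_size: int = 4
    scale_factors: tuple[int, ...] = (1, 2, 4)
    iterations: int = 60
    similarity: str = "ncc"
    lncc_radius: int = 2
    mask_dilation_vox: int = 2
    zero_outside_mask: bool = True
    convergence_tol: float = 1e-5  # LBFGS solution accuracy


# ---------------------------------------------------------------------------
# affine stage


def affine_align(
    moving: ImageVolume,
    fixed: ImageVolume,
    mask_fixed: MaskVolume | None = None,
    mode: str = "affine",
    iterations: int = 300,
) -> AffineTransform:
    """Estimate the moving→fixed world affine by intensity registration.

    Similarity is normalized cross-correlation, optionally restricted to
    ``mask_fixed``; multi-resolution (4×, 2×, 1×) with a regular-step
    gradient descent. ``mode`` may be ``"affine"`` or ``"rigid"``.
    Raises ``RuntimeError`` (with the optimizer trace attached) if the
    optimizer fails to reduce the metric.
    """
    if mask_fixed is not None and not mask_fixed.data.any():
        raise ValueError("empty fixed mask")
    f = _to_sitk(fixed.data, fixed.affine)
    m = _to_sitk(moving.data, moving.affine)

    if mode == "rigid":
        init_tx = sitk.Euler3DTransform()
    elif mode == "affine":
        init_tx = sitk.AffineTransform(3)
    else:
        raise ValueError("mode must be 'affine' or 'rigid'")
    init = sitk.CenteredTransformInitializer(
        f, m, init_tx, sitk.CenteredTransformInitializerFilter.GEOMETRY
    )

    reg = sitk.ImageRegistrationMethod()
    reg.SetInitialTransform(init, inPlace=True)
    reg.SetMetricAsCorrelation()
    reg.SetMetricSamplingStrategy(reg.NONE)
    if mask_fixed is not None:
        reg.SetMetricFixedMask(_mask_to_sitk(mask_fixed.data, mask_fixed.affine))
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-5,
        numberOfIterations=iterations,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()

    trace: list[float] = []
    level_starts: list[int] = []
    reg.AddCommand(sitk.sitkIterationEvent, lambda: trace.append(reg.GetMetricValue()))
    reg.AddCommand(sitk.sitkMultiResolutionIterationEvent,
                   lambda: level_starts.append(len(trace)))
    out = reg.Execute(f, m)
    # metric is negative NCC; metric values are only comparable within one
    # resolution level, so judge divergence on the finest level alone (and
    # tolerate flat traces: an already-aligned pair starts at the optimum)
    last = trace[level_starts[-1]:] if level_starts else trace
    if len(last) >= 2 and last[-1] > last[0] + 1e-3:
        err = RuntimeError(
            f"affine optimizer diverged: {reg.GetOptimizerStopConditionDescription()}"
        )
        err.trace = trace  # type: ignore[attr-defined]
        raise err
    fixed_to_moving = _lps_affine_to_ras(out)
    return AffineTransform(np.linalg.inv(fixed_to_moving))


def affine_skull_align(
    moving: ImageVolume,
    fixed: ImageVolume,
    skull_fixed: MaskVolume,
    dilation_vox: int = 2,
) -> AffineTransform:
    """Affine alignment restricted to the (dilated) skull.

    The skull is rigid between poses, so limiting the similarity to the
    skull avoids any bias induced by the brain shift itself. ``moving``
    is the prone scan, ``fixed`` the supine.
    """
    if not skull_fixed.data.any():
        raise ValueError("empty skull mask")
    dil = ndimage.binary_dilation(skull_fixed.data, iterations=dilation_vox)
    mask = MaskVolume(dil, skull_fixed.affine, role="skull")
    return affine_align(moving, fixed, mask_fixed=mask, mode="affine")


# ---------------------------------------------------------------------------
# elastic stage


def elastic_register(
    moving: ImageVolume,
    fixed: ImageVolume,
    brain: MaskVolume,
    params: RegistrationParams | None = None,
) -> tuple[DisplacementField, RegistrationReport]:
    """Dense PBS field by multi-level cubic B-spline FFD registration.

    ``moving`` must already be skull-aligned to ``fixed``. Returns the
    displacement field on the fixed grid (world mm, RAS) and a report
    carrying the per-iteration metric trace and a folding flag (minimum
    Jacobian determinant of id+u non-positive inside the brain; folding
    is reported, not forbidden). The report's error statistics are NaN —
    they only exist when a ground truth is available
    (:func:`evaluate_against_truth`).
    """
    params = params or RegistrationParams()
    if not brain.data.any():
        raise ValueError("empty brain mask")
    if not fixed.same_grid(brain.as_volume()):
        raise ValueError("brain mask must live on the fixed grid")

    f = _to_sitk(fixed.data, fixed.affine)
    m = _to_sitk(moving.data, moving.affine)
    dil = ndimage.binary_dilation(brain.data, iterations=params.mask_dilation_vox)

    reg = sitk.ImageRegistrationMethod()
    init = sitk.BSplineTransformInitializer(f, [params.mesh_size] * 3, order=3)
    reg.SetInitialTransformAsBSpline(
        init, inPlace=True, scaleFactors=list(params.scale_factors)
    )
    if params.similarity == "ncc":
        reg.SetMetricAsCorrelation()
    elif params.similarity == "lncc":
        reg.SetMetricAsANTSNeighborhoodCorrelation(params.lncc_radius)
    elif params.similarity == "mse":
        reg.SetMetricAsMeanSquares()
    else:
        raise ValueError(f"unknown similarity {params.similarity!r}")
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetMetricFixedMask(_mask_to_sitk(dil, brain.affine))
    reg.SetInterpolator(sitk.sitkBSpline)
    nlev = len(params.scale_factors)
    reg.SetShrinkFactorsPerLevel([2 ** (nlev - 1 - i) for i in range(nlev)])
    reg.SetSmoothingSigmasPerLevel(
        [float(2 ** (nlev - 1 - i)) / 2.0 for i in range(nlev)]
    )
    reg.SetOptimizerAsLBFGS2(
        numberOfIterations=params.iterations,
        solutionAccuracy=params.convergence_tol,
    )

    trace: list[float] = []
    reg.AddCommand(sitk.sitkIterationEvent, lambda: trace.append(reg.GetMetricValue()))
    out = reg.Execute(f, m)

    u = _dense_field(out, f)
    if not np.all(np.isfinite(u)):
        raise RuntimeError("non-finite displacement in registration output")
    if params.zero_outside_mask:
        u[~brain.data] = 0.0
    fld = DisplacementField(u, fixed.affine.copy())

    folding = bool(_min_jacobian(fld, brain) <= 0.0)
    report = RegistrationReport(
        mean=float("nan"), sd=float("nan"), p5=0.0, p95=0.0,
        n_voxels=int(brain.data.sum()), folding_detected=folding,
        convergence=tuple(trace),
    )
    return fld, report


def _min_jacobian(fld: DisplacementField, brain: MaskVolume) -> float:
    """Minimum Jacobian determinant of x ↦ x + u(x) inside the mask."""
    from .strain import deformation_gradient

    f_tensor, valid = deformation_gradient(fld, brain)
    dets = np.linalg.det(f_tensor[valid])
    return float(dets.min()) if dets.size else 1.0


def evaluate_against_truth(
    est: DisplacementField,
    truth: DisplacementField,
    brain: MaskVolume,
) -> RegistrationReport:
    """Per-voxel Euclidean endpoint error inside the brain mask.

    Reports mean, SD, 5th and 95th percentile of
    ``|u_est(x) − u_truth(x)|`` in mm.
    """
    if est.shape != truth.shape or not np.allclose(est.affine, truth.affine,
                                                   atol=1e-6):
        raise ValueError("estimate and truth grids differ")
    if est.shape != brain.shape:
        raise ValueError("mask grid differs")
    err = np.linalg.norm((est.vectors - truth.vectors)[brain.data], axis=-1)
    return RegistrationReport(
        mean=float(err.mean()),
        sd=float(err.std(ddof=0)),
        p5=float(np.percentile(err, 5)),
        p95=float(np.percentile(err, 95)),
        n_voxels=int(err.size),
    )
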