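"""Template-space normalization, vector reorientation, gravity, geometry.

Each subject's displacement field is mapped into a common template space
so subjects can be compared voxel-wise. Vectors are reoriented by the
**rotation part only** of the subject→template affine (obtained by polar
decomposition), which preserves every vector's magnitude exactly and so
keeps the correspondence between deformation and head orientation.

Gravity is fixed by scanner-bore geometry: in the neutral supine pose it
points toward the subject's posterior (0, −1, 0), in neutral prone
toward the anterior (0, 1, 0). Head-pose deviations enter as a pose
rotation; mapping through pose and normalization rotations expresses the
per-subject gravity direction in template RAS coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.linalg import polar

from .cohortstats import to_spherical
from .volio import (
    DisplacementField,
    ImageVolume,
    MaskVolume,
    ROIAtlas,
    resample_to_grid,
)


def polar_rotation(linear: np.ndarray) -> np.ndarray:
    """Proper-orthogonal rotation part of a 3×3 linear map (polar
    decomposition M = R P). Raises on reflections (det <= 0)."""
    linear = np.asarray(linear, dtype=float)
    if linear.shape == (4, 4):
        linear = linear[:3, :3]
    r, _ = polar(linear)
    if np.linalg.det(r) <= 0:
        raise ValueError("transform contains a reflection (det <= 0)")
    return r


def _matrix(transform) -> np.ndarray:
    """Accept a 4×4 array or anything exposing ``.matrix``."""
    m = getattr(transform, "matrix", transform)
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4):
        raise ValueError("expected a 4x4 affine matrix")
    return m


@dataclass(frozen=True)
class GravityDirection:
    """Unit gravity vector in template RAS plus its spherical angles."""

    vector: np.ndarray
    azimuth: float  # degrees
    elevation: float


@dataclass
class SubjectRecord:
    """One participant's volumes, masks, poses and derived quantities."""

    id: str
    supine: ImageVolume | None = None
    prone: ImageVolume | None = None
    skull: MaskVolume | None = None
    brain: MaskVolume | None = None
    atlas: ROIAtlas | None = None
    truth_field: DisplacementField | None = None  # synthetic cohorts only
    est_field: DisplacementField | None = None  # registration output
    normalized_field: DisplacementField | None = None
    to_template: np.ndarray | None = None  # 4x4 subject→template world map
    pose_supine: np.ndarray | None = None  # 3x3 head-in-scanner rotation
    pose_prone: np.ndarray | None = None
    tilt_supine: float | None = None  # degrees, + = downward
    tilt_prone: float | None = None
    gravity_supine: GravityDirection | None = None
    gravity_prone: GravityDirection | None = None
    apd: float | None = None  # mm
    mcb: float | None = None
    brain_template: MaskVolume | None = None
    atlas_template: ROIAtlas | None = None
    meta: dict = dfield(default_factory=dict)


# ---------------------------------------------------------------------------
# operations


def normalize_to_template(subject: ImageVolume, template: ImageVolume,
                          **kwargs) -> np.ndarray:
    """Estimate the subject→template world affine by intensity
    registration (delegates to the registration backend). Returns a 4×4
    matrix mapping subject world coordinates to template world
    coordinates."""
    from .register import affine_align

    return affine_align(moving=subject, fixed=template, **kwargs).matrix


def reorient_field(
    field: DisplacementField,
    transform,
    template: ImageVolume | None = None,
) -> DisplacementField:
    """Reorient (and optionally resample) a field into template space.

    Vectors v are replaced by R·v where R is the polar-decomposition
    rotation of the subject→template linear part — a pure rotation, so
    per-voxel magnitudes are preserved exactly. If ``template`` is
    given, the field's components are first resampled onto the template
    grid through the full affine (linear interpolation, zero outside).
    """
    m = _matrix(transform)
    r = polar_rotation(m[:3, :3])
    if template is not None:
        inv = np.linalg.inv(m)  # template world -> subject world
        comps = [
            resample_to_grid(
                ImageVolume(field.vectors[..., c], field.affine), template, inv
            ).data
            for c in range(3)
        ]
        vectors = np.stack(comps, axis=-1)
        affine = template.affine.copy()
    else:
        vectors = field.vectors
        affine = field.affine.copy()
    return DisplacementField(vectors @ r.T, affine)


_GRAVITY_SCANNER = {
    "supine": np.array([0.0, -1.0, 0.0]),  # toward subject's posterior
    "prone": np.array([0.0, 1.0, 0.0]),  # toward subject's anterior
}


def derive_gravity(pose_rotation: np.ndarray, position: str,
                   subject_to_template=None) -> GravityDirection:
    """Gravity direction in template RAS for one scan.

    ``pose_rotation`` maps subject-frame vectors to the scanner frame
    (neutral pose = identity); a positive rotation about the L-R axis is
    a downward head tilt. Gravity known in the scanner frame is pulled
    back to the subject frame (Rᵀ g) and pushed through the
    normalization rotation into template space.
    """
    pose = np.asarray(pose_rotation, dtype=float)
    if pose.shape != (3, 3) or not np.allclose(pose @ pose.T, np.eye(3), atol=1e-8) \
            or np.linalg.det(pose) < 0:
        raise ValueError("pose must be a proper orthogonal 3x3 rotation")
    try:
        g_scanner = _GRAVITY_SCANNER[position]
    except KeyError:
        raise ValueError(f"position must be 'prone' or 'supine', got {position!r}")
    g_subject = pose.T @ g_scanner
    if subject_to_template is not None:
        g_subject = polar_rotation(_matrix(subject_to_template)[:3, :3]) @ g_subject
    g = g_subject / np.linalg.norm(g_subject)
    s = to_spherical(g)
    return GravityDirection(vector=g, azimuth=s.azimuth, elevation=s.elevation)


def measure_geometry(intracranial: MaskVolume, to_template=None
                     ) -> tuple[float, float]:
    """Antero-posterior diameter and maximum cranial breadth, in mm.

    The mask's voxel-centre world coordinates are rotated into template
    orientation (rotation part only — sizes stay subject-native), then
    APD = P-A extent and MCB = L-R extent, each plus one voxel spacing
    (edge-to-edge rather than centre-to-centre).
    """
    if not intracranial.data.any():
        raise ValueError("empty mask")
    world = intracranial.as_volume().world_grid()[intracranial.data]
    if to_template is not None:
        r = polar_rotation(_matrix(to_template)[:3, :3])
        world = world @ r.T
    extent = world.max(axis=0) - world.min(axis=0) + intracranial.spacing
    apd = float(extent[1])
    mcb = float(extent[0])
    return apd, mcb
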