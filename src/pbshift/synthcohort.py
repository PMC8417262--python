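"""Synthetic head phantoms, ground-truth brain-shift fields, and cohorts.

Positional brain shift (PBS) is the gravity-induced sag of brain tissue
when the head changes orientation (here prone vs supine). This module
replaces MRI acquisition with a phantom generator so that every pipeline
stage can be validated against a known ground truth:

* :func:`generate_phantom` — an ellipsoidal intracranial cavity inside a
  rigid high-intensity skull shell, textured so local cross-correlation
  registration has features, with embedded "ventricle"/"nucleus"
  structures defining a synthetic ROI atlas.
* :func:`generate_pbs_field` — a smooth analytic displacement field with
  the phenomenology reported for PBS: a dominant posterior translation, a
  sagittal rotational component about an inferior-central pivot, a small
  lateral component, anterior expansion / posterior compression, and
  exact zeroes at the skull boundary and at the falx/tentorium membrane
  bands. The field is C1 inside the brain and its brain-mean magnitude is
  rescaled exactly to a target (default 0.57 mm).
* :func:`warp_volume` — creates the second deformation state so that the
  pair (phantom, warped phantom) has the generated field as its exact
  registration ground truth.
* :func:`generate_cohort` — multi-subject cohorts with prescribed
  subject-to-subject variation in cranial breadth (MCB), antero-posterior
  diameter (APD) and head tilt, linearly coupled to the PBS field.

All randomness flows from one integer seed through ``numpy``'s
``SeedSequence`` spawning, so sub-stages are independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volio import (
    DisplacementField,
    ImageVolume,
    MaskVolume,
    ROIAtlas,
    make_affine,
    rotation_about,
    write_atlas,
    write_field,
    write_mask,
    write_volume,
)

# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class Structure:
    """An ellipsoidal/spherical structure embedded in the cavity.

    ``center`` in mm relative to the cavity centre; ``radii`` the three
    semi-axes in mm (a sphere has three equal radii). ``intensity`` is the
    mean tissue intensity relative to white matter (1.0).
    """

    name: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    intensity: float = 1.0


def default_structures() -> list[Structure]:
    """Deep-brain structures mirroring the ROI set used for brain-shift
    analysis (ventricles, thalamus, basal ganglia, midbrain nuclei,
    brainstem), placed at anatomically plausible positions and sizes."""
    out: list[Structure] = []

    def lr(name, cx, cy, cz, rx, ry, rz, inten):
        out.append(Structure(f"{name}_L", (-cx, cy, cz), (rx, ry, rz), inten))
        out.append(Structure(f"{name}_R", (+cx, cy, cz), (rx, ry, rz), inten))

    lr("Vent", 10.0, 6.0, 10.0, 6.0, 24.0, 8.0, 0.45)
    lr("T", 11.0, -10.0, 3.0, 8.0, 9.0, 8.0, 1.25)
    lr("Cad", 13.0, 12.0, 9.0, 6.0, 9.0, 6.0, 1.35)
    lr("Put", 24.0, 3.0, 0.0, 7.0, 9.0, 7.0, 1.30)
    lr("Pall", 18.0, -2.0, -2.0, 5.0, 5.0, 5.0, 1.45)
    lr("STN", 10.0, -8.0, -9.0, 4.0, 4.0, 4.0, 1.55)
    lr("RN", 6.0, -14.0, -7.0, 4.0, 4.0, 4.0, 1.60)
    lr("SN", 11.0, -15.0, -12.0, 4.0, 4.0, 4.0, 1.50)
    out.append(Structure("BStem", (0.0, -20.0, -36.0), (11.0, 11.0, 13.0), 1.15))
    return out


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, texture and grid of one synthetic head.

    Default semi-axes give an intracranial cavity of maximum cranial
    breadth 137 mm (left-right) and antero-posterior diameter 176 mm,
    the population means used as calibration anchors.
    """

    semi_axes: tuple[float, float, float] = (68.5, 88.0, 60.0)  # LR, PA, IS mm
    shell_thickness: float = 6.0  # mm
    texture_length: float = 4.0  # correlation length, mm
    texture_contrast: float = 0.5  # fraction of mean intensity
    structures: tuple[Structure, ...] = tuple(default_structures())
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = 3.2  # mm/voxel, isotropic default grid
    seed: int = 0

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")


@dataclass(frozen=True)
class PBSFieldSpec:
    """Parameters of the analytic ground-truth brain-shift field.

    The raw field is
    ``rot(theta about pivot) + (0, -posterior_t, 0) + (-lateral_l, 0, 0)
    + divergence term``, multiplied by a boundary-damping envelope
    (normalised distance to the skull/falx/tentorium zero-set raised to
    ``envelope_exponent``) and rescaled so the brain-mean magnitude is
    exactly ``mean_magnitude`` mm.
    """

    theta_deg: float = 0.7  # sagittal rotation about the L-R axis
    pivot: tuple[float, float, float] = (0.0, -20.0, -45.0)  # inferior-central
    posterior_t: float = 0.12  # mm, translation toward posterior
    lateral_l: float = 0.30  # mm, signed; + = leftward
    divergence: float = 0.09  # anterior expansion / posterior compression
    envelope_exponent: float = 1.0
    envelope_saturation: float = 8.0  # tanh knee; 0 disables saturation
    mean_magnitude: float = 0.57  # mm, brain-mask mean |u|
    seed: int = 0

    def __post_init__(self):
        if self.mean_magnitude <= 0:
            raise ValueError("mean_magnitude must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Population distributions and geometry/pose → PBS couplings.

    Defaults reproduce the study conditions: cranial breadth 137 ± 6 mm,
    antero-posterior diameter 176 ± 6 mm, supine head tilt 8.3 ± 6.2
    degrees downward and prone tilt 9.9 ± 8.9 degrees; coupling slopes of
    -0.018 mm magnitude and -1.086 degrees of shift elevation per degree
    of downward supine tilt, and -2.066 degrees azimuth, -2.917 degrees
    elevation and -0.012 mm magnitude per mm of cranial breadth.
    Couplings are applied before the per-subject noise.
    """

    n_subjects: int = 11
    mcb_mean: float = 137.0
    mcb_sd: float = 6.0
    apd_mean: float = 176.0
    apd_sd: float = 6.0
    tilt_supine_mean: float = 8.3  # degrees, + = downward
    tilt_supine_sd: float = 6.2
    tilt_prone_mean: float = 9.9
    tilt_prone_sd: float = 8.9
    # coupling slopes (applied to deviations from the population mean)
    mag_per_tilt: float = -0.018  # mm / degree of supine tilt
    elev_per_tilt: float = -1.086  # degree / degree of supine tilt
    azim_per_mcb: float = -2.066  # degree / mm of MCB
    elev_per_mcb: float = -2.917  # degree / mm of MCB
    mag_per_mcb: float = -0.012  # mm / mm of MCB
    # per-subject residual noise
    noise_mag_sd: float = 0.03  # mm
    noise_angle_sd: float = 1.5  # degrees
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")


# ---------------------------------------------------------------------------
# phantom generation


def _default_affine(shape, spacing) -> np.ndarray:
    """Isotropic RAS affine centred on the world origin."""
    sp = np.full(3, float(spacing))
    origin = -(np.asarray(shape) - 1) / 2.0 * sp
    return make_affine(np.diag(sp), origin)


def _ellipsoid_mask(world: np.ndarray, center, semi) -> np.ndarray:
    d = (world - np.asarray(center)) / np.asarray(semi)
    return np.sum(d * d, axis=-1) <= 1.0


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[ImageVolume, MaskVolume, MaskVolume, ROIAtlas]:
    """Build one textured head phantom.

    Returns ``(volume, skull_mask, brain_mask, atlas)``. The skull shell
    carries the highest intensity band; the brain interior is smoothed
    seeded noise superimposed on per-structure mean intensities; atlas
    structures are mutually disjoint by construction (later structures
    are carved out of earlier tissue, never the reverse).
    """
    a = np.asarray(spec.semi_axes, dtype=float)
    for s in spec.structures:
        c = np.abs(np.asarray(s.center))
        r = np.asarray(s.radii)
        if np.sum(((c + r) / a) ** 2) >= 1.0 and np.any((c + r) >= a):
            raise ValueError(f"structure {s.name} escapes the intracranial cavity")

    affine = _default_affine(spec.shape, spec.spacing)
    tmp = ImageVolume(np.zeros(spec.shape, dtype=np.float32), affine)
    world = tmp.world_grid()

    intracranial = _ellipsoid_mask(world, (0, 0, 0), a)
    outer = _ellipsoid_mask(world, (0, 0, 0), a + spec.shell_thickness)
    skull = outer & ~intracranial

    # brain = cavity eroded by one voxel (CSF gap against the skull)
    brain = ndimage.binary_erosion(intracranial, iterations=1)

    # tissue mean intensities: WM baseline 1, skull brightest band
    intensity = np.zeros(spec.shape, dtype=np.float64)
    intensity[intracranial] = 1.0
    labels = np.zeros(spec.shape, dtype=np.int32)
    table: dict[int, str] = {}

    # GM = cortical shell (within gm_depth of the cavity boundary)
    gm_depth = max(6.0, 1.5 * spec.spacing)
    dist_in = ndimage.distance_transform_edt(
        intracranial, sampling=[spec.spacing] * 3
    )
    gm = brain & (dist_in <= gm_depth + spec.spacing)
    wm = brain & ~gm
    right = world[..., 0] >= 0.0
    labels[gm & ~right], table[1] = 1, "GM_L"
    labels[gm & right], table[2] = 2, "GM_R"
    labels[wm & ~right], table[3] = 3, "WM_L"
    labels[wm & right], table[4] = 4, "WM_R"
    intensity[gm] = 0.85

    next_id = 5
    for s in spec.structures:
        m = _ellipsoid_mask(world, s.center, s.radii) & brain
        labels[m] = next_id
        table[next_id] = s.name
        intensity[m] = s.intensity
        next_id += 1

    # seeded smooth texture so local similarity has features everywhere
    if spec.texture_contrast > 0.0:
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 0x9E3779B9]))
        noise = rng.standard_normal(spec.shape)
        sigma_vox = spec.texture_length / spec.spacing
        noise = ndimage.gaussian_filter(noise, sigma_vox)
        noise /= max(noise.std(), 1e-12)
        data = intensity * (1.0 + spec.texture_contrast * noise)
    else:
        data = intensity.copy()
    # tissue stays strictly below the shell band; texture tails clipped
    data = np.clip(data, 0.0, 2.0)
    data[~intracranial] = 0.0
    data[skull] = 2.4  # rigid high-intensity shell dominates the histogram

    vol = ImageVolume(data, affine)
    return (
        vol,
        MaskVolume(skull, affine.copy(), role="skull"),
        MaskVolume(brain, affine.copy(), role="brain"),
        ROIAtlas(labels, affine.copy(), table),
    )


def intracranial_mask(skull: MaskVolume) -> MaskVolume:
    """Skull-interior cavity mask (fill the shell, subtract it).

    The shell is morphologically closed first so that a field of view
    that truncates the outer skull surface does not leave an open cap
    through which the fill would leak.
    """
    closed = ndimage.binary_closing(skull.data, iterations=2)
    filled = ndimage.binary_fill_holes(closed)
    return MaskVolume(filled & ~skull.data, skull.affine.copy(),
                      role="intracranial")


# ---------------------------------------------------------------------------
# ground-truth PBS field


def _membrane_bands(brain: MaskVolume) -> np.ndarray:
    """Falx (superior mid-sagittal plane) and tentorium (posterior
    horizontal plane) bands, one voxel-spacing thick, as zero-shift sets."""
    world = brain.as_volume().world_grid()
    w = world[brain.data]
    lo, hi = w.min(axis=0), w.max(axis=0)
    c = (lo + hi) / 2.0
    thick = float(np.max(brain.spacing)) * 0.6
    falx = (np.abs(world[..., 0] - c[0]) <= thick) & (world[..., 2] >= c[2])
    z_tent = c[2] - 0.45 * (hi[2] - c[2]) - 0.2 * (c[2] - lo[2])
    tent = (np.abs(world[..., 2] - z_tent) <= thick) & (world[..., 1] <= c[1])
    return (falx | tent) & brain.data


def generate_pbs_field(spec: PBSFieldSpec, brain: MaskVolume) -> DisplacementField:
    """Analytic boundary-damped PBS field on the brain mask's grid.

    The returned field is exactly zero outside the brain mask and on the
    falx/tentorium bands, C1-smooth inside, and has brain-mean magnitude
    exactly ``spec.mean_magnitude`` mm. With ``posterior_t > 0`` the mean
    posterior-anterior component is negative (a net posterior shift);
    with ``divergence > 0`` the hydrostatic strain is positive in the
    anterior half and negative in the posterior half.
    """
    if not brain.data.any():
        raise ValueError("brain mask is empty")
    world = brain.as_volume().world_grid()
    w = world[brain.data]
    centroid = w.mean(axis=0)
    pa_half = (w[:, 1].max() - w[:, 1].min()) / 2.0

    # boundary-damping envelope: distance to {outside brain, falx, tentorium}
    zero_set = ~brain.data | _membrane_bands(brain)
    moving = ~zero_set
    dist = ndimage.distance_transform_edt(moving, sampling=brain.spacing)
    dmax = dist.max()
    if dmax <= 0:
        raise ValueError("membranes leave no moving tissue")
    env = (dist / dmax) ** spec.envelope_exponent
    if spec.envelope_saturation > 0:
        # saturate toward a deep-interior plateau: keeps the zero boundary
        # and C1 smoothness while spreading displacement over the depth
        # (deep structures shift more than cortex, but not excessively so)
        k = spec.envelope_saturation
        env = np.tanh(k * env) / np.tanh(k)

    # raw kinematics (mm) evaluated at world coordinates
    rel = world - np.asarray(spec.pivot)
    rot = rotation_about("x", spec.theta_deg) - np.eye(3)
    u = rel @ rot.T
    u[..., 1] += -spec.posterior_t
    u[..., 0] += -spec.lateral_l
    # convex-in-y term: d(u_y)/dy > 0 anterior of the centroid (expansion),
    # < 0 posterior (compression); centred so it adds no net translation
    dy = world[..., 1] - centroid[1]
    dy2_mean = float(np.mean((w[:, 1] - centroid[1]) ** 2))
    u[..., 1] += spec.divergence * (dy**2 - dy2_mean) / max(pa_half, 1e-9)

    u *= env[..., None]
    u[~brain.data] = 0.0

    mean_mag = np.linalg.norm(u[brain.data], axis=-1).mean()
    if mean_mag <= 0:
        raise ValueError("degenerate field (all-zero inside the mask)")
    u *= spec.mean_magnitude / mean_mag
    return DisplacementField(u, brain.affine.copy())


def warp_volume(vol: ImageVolume, fld: DisplacementField,
                order: int = 3) -> ImageVolume:
    """Backward-warp ``vol`` through ``fld``: out(x) = vol(x + u(x)).

    The pair ``(vol, warp_volume(vol, fld))`` then has ``fld`` as the
    exact ground truth of a registration with moving=``vol`` and
    fixed=the warped volume (moving(x + u(x)) = fixed(x) identically).
    """
    if vol.shape != fld.shape or not np.allclose(vol.affine, fld.affine, atol=1e-6):
        raise ValueError("field must live on the volume's grid")
    src_world = vol.world_grid() + fld.vectors
    src_idx = vol.world_to_voxel(src_world)
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float),
        [src_idx[..., 0], src_idx[..., 1], src_idx[..., 2]],
        order=order, mode="constant", cval=0.0,
    )
    return ImageVolume(out, vol.affine.copy())


# ---------------------------------------------------------------------------
# cohorts


def _rotate_field_vectors(fld: DisplacementField, rot: np.ndarray) -> DisplacementField:
    return DisplacementField(fld.vectors @ rot.T, fld.affine.copy())


def _rotation_between(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Minimal rotation carrying direction v onto direction w (Rodrigues)."""
    v = np.asarray(v, float) / np.linalg.norm(v)
    w = np.asarray(w, float) / np.linalg.norm(w)
    axis = np.cross(v, w)
    s = np.linalg.norm(axis)
    c = float(np.dot(v, w))
    if s < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(v, v)
    k = axis / s
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + s * kx + (1 - c) * (kx @ kx)


def generate_cohort(
    cspec: CohortSpec,
    pspec: PhantomSpec | None = None,
    fspec: PBSFieldSpec | None = None,
    volumes: bool = True,
):
    """Draw a cohort of subjects with coupled geometry, pose and shift.

    Per subject: cranial breadth (MCB) and antero-posterior diameter
    (APD) rescale the phantom's L-R / P-A semi-axes; the supine head tilt
    rotates the scanner-frame pose about the L-R axis; the PBS field's
    mean magnitude, elevation and azimuth are shifted linearly from the
    population values by the coupling slopes (before noise). Direction
    couplings are applied as exact rotations of the subject's field and
    the magnitude coupling through the field's mean-magnitude rescale, so
    the built-in slopes are exact up to the configured noise.

    With ``volumes=False`` only masks, truth fields and metadata are
    generated (no texture, no warped prone volume) — sufficient for
    statistics and parameter-recovery studies.

    Returns a list of :class:`pbshift.normalize.SubjectRecord`.
    """
    from .normalize import SubjectRecord, derive_gravity

    from .cohortstats import from_spherical, to_spherical

    pspec = pspec or PhantomSpec()
    fspec = fspec or PBSFieldSpec()
    ss = np.random.SeedSequence(cspec.seed)
    draw_rng = np.random.default_rng(ss.spawn(1)[0])
    subject_seeds = ss.spawn(cspec.n_subjects)

    # cohort-reference shift direction: the field realised on the
    # mean-geometry phantom; per-subject directions are set relative to
    # it so geometry rescaling cannot leak into the built-in couplings
    ref_pspec = replace(
        pspec,
        semi_axes=(cspec.mcb_mean / 2.0, cspec.apd_mean / 2.0, pspec.semi_axes[2]),
        texture_contrast=0.0,
    )
    _, _, ref_brain, _ = generate_phantom(ref_pspec)
    ref_field = generate_pbs_field(fspec, ref_brain)
    ref_sph = to_spherical(ref_field.vectors[ref_brain.data].mean(axis=0))

    records: list[SubjectRecord] = []
    for i in range(cspec.n_subjects):
        rng = np.random.default_rng(subject_seeds[i])
        mcb = draw_rng.normal(cspec.mcb_mean, cspec.mcb_sd)
        apd = draw_rng.normal(cspec.apd_mean, cspec.apd_sd)
        tilt_s = draw_rng.normal(cspec.tilt_supine_mean, cspec.tilt_supine_sd)
        tilt_p = draw_rng.normal(cspec.tilt_prone_mean, cspec.tilt_prone_sd)

        d_tilt = tilt_s - cspec.tilt_supine_mean
        d_mcb = mcb - cspec.mcb_mean
        mag = (fspec.mean_magnitude + cspec.mag_per_tilt * d_tilt
               + cspec.mag_per_mcb * d_mcb
               + rng.normal(0.0, cspec.noise_mag_sd))
        mag = max(mag, 0.05)
        d_elev = (cspec.elev_per_tilt * d_tilt + cspec.elev_per_mcb * d_mcb
                  + rng.normal(0.0, cspec.noise_angle_sd))
        d_azim = (cspec.azim_per_mcb * d_mcb
                  + rng.normal(0.0, cspec.noise_angle_sd))

        sub_pspec = replace(
            pspec,
            semi_axes=(mcb / 2.0, apd / 2.0, pspec.semi_axes[2]),
            seed=int(rng.integers(0, 2**31 - 1)),
            texture_contrast=pspec.texture_contrast if volumes else 0.0,
        )
        vol, skull, brain, atlas = generate_phantom(sub_pspec)

        fld = generate_pbs_field(replace(fspec, mean_magnitude=mag), brain)
        base = fld.vectors[brain.data].mean(axis=0)
        target = from_spherical(ref_sph.azimuth + d_azim,
                                ref_sph.elevation + d_elev, 1.0)
        fld = _rotate_field_vectors(fld, _rotation_between(base, target))

        pose_supine = rotation_about("x", tilt_s)
        pose_prone = rotation_about("x", tilt_p)

        # template alignment ground truth: subject = pose o anisotropic scale
        scale = np.diag([mcb / cspec.mcb_mean, apd / cspec.apd_mean, 1.0])
        to_template = make_affine(np.linalg.inv(scale), np.zeros(3))

        # the generated phantom is the prone-aligned reference state; the
        # supine state is its backward warp through the truth field, so
        # that registration (moving=prone, fixed=supine) has exactly
        # `fld` as ground truth: prone(x + u(x)) = supine(x) with u = fld
        supine = warp_volume(vol, fld) if volumes else vol

        rec = SubjectRecord(
            id=f"sub-{i + 1:02d}",
            supine=supine,
            prone=vol if volumes else None,
            skull=skull,
            brain=brain,
            atlas=atlas,
            truth_field=fld,
            to_template=to_template,
            pose_supine=pose_supine,
            pose_prone=pose_prone,
            tilt_supine=float(tilt_s),
            tilt_prone=float(tilt_p),
        )
        # ground-truth geometry of the drawn cavity; the normalization
        # stage re-measures these from the voxelized masks when run
        rec.apd, rec.mcb = float(apd), float(mcb)
        rec.gravity_supine = derive_gravity(pose_supine, "supine", to_template)
        rec.gravity_prone = derive_gravity(pose_prone, "prone", to_template)
        records.append(rec)
    return records


def write_cohort(records, out_dir: str | Path) -> None:
    """Write a cohort as the on-disk layout consumed by the real-study
    pipeline: sub-XX/{supine,prone,skull,brain,atlas,truth_field}.nii.gz
    plus atlas_labels.tsv and meta.json per subject."""
    out_dir = Path(out_dir)
    for rec in records:
        d = out_dir / rec.id
        d.mkdir(parents=True, exist_ok=True)
        write_volume(rec.supine, d / "supine.nii.gz")
        if rec.prone is not None:
            write_volume(rec.prone, d / "prone.nii.gz")
        write_mask(rec.skull, d / "skull.nii.gz")
        write_mask(rec.brain, d / "brain.nii.gz")
        write_atlas(rec.atlas, d / "atlas.nii.gz", d / "atlas_labels.tsv")
        if rec.truth_field is not None:
            write_field(rec.truth_field, d / "truth_field.nii.gz")
        meta = {
            "id": rec.id,
            "tilt_supine": rec.tilt_supine,
            "tilt_prone": rec.tilt_prone,
            "pose_supine": np.asarray(rec.pose_supine).tolist(),
            "pose_prone": np.asarray(rec.pose_prone).tolist(),
            "apd": rec.apd,
            "mcb": rec.mcb,
        }
        if rec.to_template is not None:
            meta["to_template"] = np.asarray(rec.to_template).tolist()
        (d / "meta.json").write_text(json.dumps(meta, indent=1))
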