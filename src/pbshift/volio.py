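"""Volume and field I/O, coordinate conventions, mask/atlas primitives.

All stages of the pipeline exchange three grid-based containers:

* :class:`ImageVolume` — a 3-D scalar grid plus a 4×4 voxel-index → world
  affine in RAS millimetres (+x right, +y anterior, +z superior).
* :class:`MaskVolume` / :class:`ROIAtlas` — binary and integer label grids
  sharing the geometry of a companion volume.
* :class:`DisplacementField` — a per-voxel 3-vector field whose components
  are world-frame millimetres (never voxel units), so anisotropic grids
  need no special-casing downstream.

Files are NIfTI-1 (via nibabel); any on-disk orientation is canonicalised
to RAS on read. Voxel indices are 0-based and the affine maps index
(0,0,0) to that voxel's centre (the NIfTI convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


# --------------------------------------------------------------------------
# containers


@dataclass
class ImageVolume:
    """3-D intensity grid with a voxel→world (RAS, mm) affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm along each index axis (column norms)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to (..., 3) world RAS mm."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_grid(self) -> np.ndarray:
        """(X, Y, Z, 3) array of world coordinates of all voxel centres."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.voxel_to_world(idx)

    def same_grid(self, other: "ImageVolume | MaskVolume | DisplacementField") -> bool:
        return self.shape == tuple(other.shape[:3]) and np.allclose(
            self.affine, other.affine, atol=1e-6
        )


@dataclass
class MaskVolume:
    """Binary grid on the same geometry as a companion :class:`ImageVolume`.

    ``role`` is one of ``{"brain", "skull", "intracranial"}``.
    """

    data: np.ndarray
    affine: np.ndarray
    role: str = "brain"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def as_volume(self) -> ImageVolume:
        return ImageVolume(self.data.astype(np.float32), self.affine)


@dataclass
class ROIAtlas:
    """Integer label grid plus a label-id → name table.

    0 is background; left/right variants of a structure carry distinct
    ids with ``_L`` / ``_R`` name suffixes (e.g. ``T_L``, ``T_R``).
    """

    labels: np.ndarray
    affine: np.ndarray
    table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(np.int32)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.table)
        if missing:
            raise ValueError(f"label ids {sorted(missing)} missing from table")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def names(self) -> list[str]:
        return sorted(set(self.table.values()))

    def base_names(self) -> list[str]:
        """Structure names with the _L/_R suffix stripped."""
        return sorted({n.rsplit("_", 1)[0] if n.endswith(("_L", "_R")) else n
                       for n in self.table.values()})


@dataclass
class DisplacementField:
    """Per-voxel displacement u(x), world-RAS components in mm.

    Lives on the reference (fixed/supine) grid. Convention matches the
    registration contract: for the aligned prone/supine pair,
    ``moving(x + u(x)) ≈ fixed(x)`` with x and u in world mm, i.e. u(x)
    carries voxel x of the supine grid to the corresponding material
    point's prone-aligned position.
    """

    vectors: np.ndarray  # (X, Y, Z, 3)
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("vectors must have shape (X, Y, Z, 3)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)


# --------------------------------------------------------------------------
# NIfTI I/O


def _canonical(img: nib.Nifti1Image) -> nib.Nifti1Image:
    return nib.as_closest_canonical(img)


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI volume, canonicalised to RAS orientation.

    Raises ``ValueError`` for a non-3-D payload and lets nibabel's I/O
    errors propagate for unreadable files.
    """
    img = _canonical(nib.load(str(path)))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D payload, got {data.ndim}-D")
    return ImageVolume(data.astype(np.float64), np.asarray(img.affine))


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine),
             str(path))


def read_mask(path: str | Path, role: str = "brain") -> MaskVolume:
    v = read_volume(path)
    return MaskVolume(v.data > 0.5, v.affine, role=role)


def write_mask(mask: MaskVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path))


def read_field(path: str | Path) -> DisplacementField:
    """Read a 3-component vector NIfTI (shape X,Y,Z,3 or X,Y,Z,1,3)."""
    img = _canonical(nib.load(str(path)))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 5 and data.shape[3] == 1:
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: expected a 3-component vector image")
    return DisplacementField(data, np.asarray(img.affine))


def write_field(fld: DisplacementField, path: str | Path) -> None:
    img = nib.Nifti1Image(fld.vectors.astype(np.float32), fld.affine)
    img.header.set_intent("vector")
    nib.save(img, str(path))


def read_atlas(path: str | Path, table_path: str | Path) -> ROIAtlas:
    """Read a label NIfTI plus its id\\tname TSV table."""
    v = read_volume(path)
    table: dict[int, str] = {}
    for line in Path(table_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        lab, name = line.split("\t")
        table[int(lab)] = name
    return ROIAtlas(np.rint(v.data).astype(np.int32), v.affine, table)


def write_atlas(atlas: ROIAtlas, path: str | Path, table_path: str | Path) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine), str(path))
    Path(table_path).write_text(
        "".join(f"{i}\t{n}\n" for i, n in sorted(atlas.table.items()))
    )


# --------------------------------------------------------------------------
# resampling and ROI helpers


def resample_to_grid(
    vol: ImageVolume,
    target: ImageVolume,
    transform: np.ndarray | None = None,
    interpolation: str = "linear",
) -> ImageVolume:
    """Resample ``vol`` onto ``target``'s grid through a world-space map.

    ``transform`` is a 4×4 map from **target world coordinates to source
    world coordinates** (ITK resampling semantics): the output intensity
    at target voxel centre x is ``vol(transform @ x)``. ``None`` means
    identity. ``interpolation`` is ``"linear"`` for intensities or
    ``"nearest"`` for masks/atlases (labels stay labels).
    """
    if transform is None:
        transform = np.eye(4)
    transform = np.asarray(transform, dtype=float)
    if abs(np.linalg.det(transform[:3, :3])) < 1e-12:
        raise ValueError("singular transform")
    # target voxel index -> source voxel index, one combined affine
    m = np.linalg.inv(vol.affine) @ transform @ target.affine
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in target.shape], indexing="ij"), axis=-1
    )
    src = idx @ m[:3, :3].T + m[:3, 3]
    order = {"linear": 1, "nearest": 0}[interpolation]
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float),
        [src[..., 0], src[..., 1], src[..., 2]],
        order=order,
        mode="constant",
        cval=0.0,
    )
    return ImageVolume(out, target.affine.copy())


def resample_mask(mask: MaskVolume, target: ImageVolume,
                  transform: np.ndarray | None = None) -> MaskVolume:
    out = resample_to_grid(mask.as_volume(), target, transform, "nearest")
    return MaskVolume(out.data > 0.5, target.affine.copy(), role=mask.role)


def resample_atlas(atlas: ROIAtlas, target: ImageVolume,
                   transform: np.ndarray | None = None) -> ROIAtlas:
    vol = ImageVolume(atlas.labels.astype(np.float64), atlas.affine)
    out = resample_to_grid(vol, target, transform, "nearest")
    return ROIAtlas(np.rint(out.data).astype(np.int32), target.affine.copy(),
                    dict(atlas.table))


def _resolve_roi_ids(atlas: ROIAtlas, name: str) -> list[int]:
    ids = [i for i, n in atlas.table.items()
           if n == name or (n.endswith(("_L", "_R")) and n[:-2] == name)]
    return sorted(ids)


def roi_mask(atlas: ROIAtlas, names: list[str] | str) -> MaskVolume:
    """Union mask of the requested ROI names.

    A base name (``"T"``) resolves to both hemispheric labels
    (``T_L``, ``T_R``); compound ROIs are expressed by passing several
    names (e.g. ``["STN", "RN", "SN"]``).
    """
    if isinstance(names, str):
        names = [names]
    ids: list[int] = []
    for name in names:
        found = _resolve_roi_ids(atlas, name)
        if not found:
            raise KeyError(
                f"unknown ROI {name!r}; known: {', '.join(atlas.names())}"
            )
        ids.extend(found)
    out = np.isin(atlas.labels, ids)
    return MaskVolume(out, atlas.affine.copy(), role="brain")


# --------------------------------------------------------------------------
# small affine helpers shared across modules


def rotation_about(axis: str, degrees: float) -> np.ndarray:
    """3×3 right-handed rotation about a world axis ('x'|'y'|'z')."""
    a = np.deg2rad(degrees)
    c, s = np.cos(a), np.sin(a)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    raise ValueError(f"unknown axis {axis!r}")


def make_affine(linear: np.ndarray, translation: np.ndarray) -> np.ndarray:
    out = np.eye(4)
    out[:3, :3] = linear
    out[:3, 3] = translation
    return out
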