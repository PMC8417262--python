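"""Green–Lagrange strain analysis of a displacement field.

The deformation gradient F = ∂u/∂x + I is evaluated voxel-wise from the
displacement field u (world mm) by spacing-aware finite differences, and
the Green–Lagrange tensor

    E = ½ (FᵀF − I)

interprets the deformation differentially, discarding any rigid-body
motion (E vanishes identically when F is a rotation). E is further
partitioned into a hydrostatic part, representing volume change at
small strains,

    E_hyd = (E_xx + E_yy + E_zz) / 3,

and a trace-free deviatoric part representing shape change,

    E_dev = E − E_hyd · I.

Finite differences are central where both along-axis neighbours are
inside the mask, one-sided where only one is, and a voxel with no
in-mask neighbour along some axis is flagged invalid and excluded from
all statistics (never zero-filled). Central differences in world units
are exact for displacement fields up to quadratic in position. No
pre-smoothing is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volio import DisplacementField, MaskVolume


@dataclass
class StrainField:
    """Voxel-wise deformation gradient and strain decomposition.

    ``F``, ``E``, ``E_dev`` have shape (X, Y, Z, 3, 3); ``E_hyd`` is the
    scalar (X, Y, Z) hydrostatic strain; ``valid`` marks voxels with
    full finite-difference support. All strains are dimensionless
    (mm/mm); multiply by 100 for percent.
    """

    F: np.ndarray
    E: np.ndarray
    E_hyd: np.ndarray
    E_dev: np.ndarray
    valid: np.ndarray
    affine: np.ndarray

    def diagonals(self) -> np.ndarray:
        """(X, Y, Z, 3) array of E_xx, E_yy, E_zz."""
        return np.stack([self.E[..., i, i] for i in range(3)], axis=-1)


def deformation_gradient(
    field: DisplacementField, brain: MaskVolume
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise F = ∂u/∂x + I in world units.

    Returns ``(F, valid)``. Differences are taken along voxel axes with
    the mask-aware central/one-sided stencil described in the module
    docstring, then mapped to world derivatives through the inverse of
    the affine's linear part (so anisotropic or oblique grids are
    handled uniformly).
    """
    if field.shape != brain.shape:
        raise ValueError("field and mask grids differ")
    m = brain.data
    if not m.any():
        raise ValueError("mask is empty")

    u = field.vectors  # (X, Y, Z, 3)
    didx = np.zeros(field.shape + (3, 3))  # [..., i, j] = du_i/didx_j
    valid = m.copy()
    for ax in range(3):
        up = np.zeros_like(m)
        dn = np.zeros_like(m)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        up[tuple(sl_lo)] = m[tuple(sl_hi)]  # neighbour at +1 in mask
        dn[tuple(sl_hi)] = m[tuple(sl_lo)]  # neighbour at -1 in mask

        u_up = np.zeros_like(u)
        u_dn = np.zeros_like(u)
        u_up[tuple(sl_lo)] = u[tuple(sl_hi)]
        u_dn[tuple(sl_hi)] = u[tuple(sl_lo)]

        central = m & up & dn
        fwd = m & up & ~dn
        bwd = m & ~up & dn
        diff = np.zeros_like(u)
        diff[central] = (u_up[central] - u_dn[central]) / 2.0
        diff[fwd] = u_up[fwd] - u[fwd]
        diff[bwd] = u[bwd] - u_dn[bwd]
        didx[..., :, ax] = diff
        valid &= up | dn

    inv_a3 = np.linalg.inv(field.affine[:3, :3])
    grad_world = didx @ inv_a3  # du_i/dx_world_j, dimensionless
    f_tensor = grad_world + np.eye(3)
    f_tensor[~valid] = np.eye(3)
    return f_tensor, valid


def green_lagrange(f_tensor: np.ndarray) -> np.ndarray:
    """E = ½(FᵀF − I), symmetric by construction."""
    ft_f = np.einsum("...ki,...kj->...ij", f_tensor, f_tensor)
    return 0.5 * (ft_f - np.eye(3))


def partition_strain(e_tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hydrostatic/deviatoric split: E_hyd = tr(E)/3, E_dev = E − E_hyd·I."""
    e_hyd = np.trace(e_tensor, axis1=-2, axis2=-1) / 3.0
    e_dev = e_tensor - e_hyd[..., None, None] * np.eye(3)
    return e_hyd, e_dev


def compute_strain(field: DisplacementField, brain: MaskVolume) -> StrainField:
    """Full pipeline: F, E and the hydrostatic/deviatoric partition."""
    f_tensor, valid = deformation_gradient(field, brain)
    e_tensor = green_lagrange(f_tensor)
    e_hyd, e_dev = partition_strain(e_tensor)
    return StrainField(
        F=f_tensor, E=e_tensor, E_hyd=e_hyd, E_dev=e_dev,
        valid=valid, affine=field.affine.copy(),
    )


def strain_percent_maps(sf: StrainField) -> dict[str, np.ndarray]:
    """Reporting maps in percent, zeroed outside the validity mask.

    Keys: ``E_xx``, ``E_yy``, ``E_zz`` (diagonal strain components along
    L-R, P-A, I-S), ``E_hyd``, and the deviatoric diagonals
    ``E_dev_xx``, ``E_dev_yy``, ``E_dev_zz``.
    """
    v = sf.valid
    out: dict[str, np.ndarray] = {}
    for idx, name in enumerate(("E_xx", "E_yy", "E_zz")):
        arr = sf.E[..., idx, idx] * 100.0
        arr = np.where(v, arr, 0.0)
        out[name] = arr
    out["E_hyd"] = np.where(v, sf.E_hyd * 100.0, 0.0)
    for idx, name in enumerate(("E_dev_xx", "E_dev_yy", "E_dev_zz")):
        out[name] = np.where(v, sf.E_dev[..., idx, idx] * 100.0, 0.0)
    return out
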