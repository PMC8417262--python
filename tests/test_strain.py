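import numpy as np
import pytest

from pbshift.strain import (
    StrainField,
    compute_strain,
    deformation_gradient,
    green_lagrange,
    partition_strain,
    strain_percent_maps,
)
from pbshift.volio import DisplacementField, MaskVolume, make_affine, rotation_about


def _field_from_function(fn, shape=(9, 9, 9), spacing=(1.0, 1.0, 1.0),
                         origin=(0.0, 0.0, 0.0)):
    affine = make_affine(np.diag(spacing), origin)
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"),
                   axis=-1).astype(float)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    u = fn(world)
    fld = DisplacementField(u, affine)
    mask = MaskVolume(np.ones(shape, bool), affine)
    return fld, mask, world


def brute_force_strain(u, mask, spacing):
    """Independent per-voxel oracle: loops, explicit stencils, Eqs. as
    written (F = du/dx + I, E = (FtF - I)/2, hyd/dev split)."""
    shape = u.shape[:3]
    F = np.zeros(shape + (3, 3))
    E = np.zeros(shape + (3, 3))
    hyd = np.zeros(shape)
    dev = np.zeros(shape + (3, 3))
    valid = np.zeros(shape, bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if not mask[i, j, k]:
                    continue
                grad = np.zeros((3, 3))
                ok = True
                for ax, h in enumerate(spacing):
                    lo = [i, j, k]
                    hi = [i, j, k]
                    lo[ax] -= 1
                    hi[ax] += 1
                    has_lo = lo[ax] >= 0 and mask[tuple(lo)]
                    has_hi = hi[ax] < shape[ax] and mask[tuple(hi)]
                    if has_lo and has_hi:
                        d = (u[tuple(hi)] - u[tuple(lo)]) / (2 * h)
                    elif has_hi:
                        d = (u[tuple(hi)] - u[i, j, k]) / h
                    elif has_lo:
                        d = (u[i, j, k] - u[tuple(lo)]) / h
                    else:
                        ok = False
                        break
                    grad[:, ax] = d
                if not ok:
                    continue
                valid[i, j, k] = True
                f = grad + np.eye(3)
                e = 0.5 * (f.T @ f - np.eye(3))
                F[i, j, k] = f
                E[i, j, k] = e
                hyd[i, j, k] = np.trace(e) / 3.0
                dev[i, j, k] = e - np.trace(e) / 3.0 * np.eye(3)
    return F, E, hyd, dev, valid


class TestDeformationGradient:
    def test_zero_field_gives_identity(self):
        fld, mask, _ = _field_from_function(lambda w: np.zeros_like(w))
        F, valid = deformation_gradient(fld, mask)
        assert valid.all()
        np.testing.assert_allclose(F, np.broadcast_to(np.eye(3), F.shape),
                                   atol=1e-15)

    def test_linear_field_exact(self):
        A = np.array([[0.01, 0.002, 0.0],
                      [-0.003, 0.02, 0.001],
                      [0.0, 0.004, -0.01]])
        fld, mask, _ = _field_from_function(
            lambda w: w @ A.T, spacing=(0.8, 0.75, 0.75))
        F, valid = deformation_gradient(fld, mask)
        np.testing.assert_allclose(
            F[valid], np.broadcast_to(A + np.eye(3), F[valid].shape), atol=1e-12)

    def test_quadratic_field_exact_at_central_voxels(self):
        # u_i = w_i^2 / 100: du_i/dx_i = w_i/50, central diffs exact on quadratics
        fld, mask, world = _field_from_function(lambda w: w**2 / 100.0,
                                                spacing=(1.0, 2.0, 1.5))
        F, _ = deformation_gradient(fld, mask)
        interior = np.zeros(mask.shape, bool)
        interior[1:-1, 1:-1, 1:-1] = True
        expected = world / 50.0
        for ax in range(3):
            np.testing.assert_allclose(
                F[interior][:, ax, ax], expected[interior][:, ax] + 1.0,
                atol=1e-12)

    def test_masked_edge_voxels_flagged_invalid(self):
        shape = (5, 5, 5)
        mask_arr = np.zeros(shape, bool)
        mask_arr[2, 2, 2] = True  # isolated voxel: no neighbours at all
        fld = DisplacementField(np.zeros(shape + (3,)), np.eye(4))
        _, valid = deformation_gradient(fld, MaskVolume(mask_arr, np.eye(4)))
        assert not valid[2, 2, 2]

    def test_empty_mask_rejected(self):
        fld = DisplacementField(np.zeros((4, 4, 4, 3)), np.eye(4))
        with pytest.raises(ValueError, match="empty"):
            deformation_gradient(fld, MaskVolume(np.zeros((4, 4, 4), bool),
                                                 np.eye(4)))


class TestGreenLagrange:
    def test_identity_gives_zero(self):
        E = green_lagrange(np.eye(3)[None])
        np.testing.assert_allclose(E, 0.0, atol=1e-16)

    @pytest.mark.parametrize("axis,deg", [("z", 10.0), ("x", 37.0), ("y", -5.0)])
    def test_pure_rotation_gives_zero_strain(self, axis, deg):
        R = rotation_about(axis, deg)
        E = green_lagrange(R[None])
        np.testing.assert_allclose(E, 0.0, atol=1e-12)

    def test_uniaxial_stretch(self):
        F = np.diag([1.1, 1.0, 1.0])
        E = green_lagrange(F[None])[0]
        np.testing.assert_allclose(E, np.diag([0.105, 0.0, 0.0]), atol=1e-12)


class TestPartition:
    def test_isotropic(self):
        hyd, dev = partition_strain(0.01 * np.eye(3)[None])
        assert hyd[0] == pytest.approx(0.01)
        np.testing.assert_allclose(dev[0], 0.0, atol=1e-15)

    def test_uniaxial(self):
        hyd, dev = partition_strain(np.diag([0.03, 0.0, 0.0])[None])
        assert hyd[0] == pytest.approx(0.01)
        np.testing.assert_allclose(dev[0], np.diag([0.02, -0.01, -0.01]),
                                   atol=1e-15)

    def test_deviatoric_traceless_for_random_tensors(self, rng):
        e = rng.normal(size=(50, 3, 3))
        e = 0.5 * (e + np.transpose(e, (0, 2, 1)))
        _, dev = partition_strain(e)
        np.testing.assert_allclose(np.trace(dev, axis1=-2, axis2=-1), 0.0,
                                   atol=1e-12)


class TestPipelineAgainstBruteForce:
    def test_random_patch_matches_oracle_to_machine_precision(self, rng):
        spacing = (0.8, 0.75, 0.75)
        for _ in range(3):
            u = rng.normal(scale=0.1, size=(9, 9, 9, 3))
            mask_arr = rng.random((9, 9, 9)) > 0.2
            fld = DisplacementField(u, make_affine(np.diag(spacing), [0, 0, 0]))
            mask = MaskVolume(mask_arr, fld.affine)
            if not mask_arr.any():
                continue
            sf = compute_strain(fld, mask)
            F0, E0, hyd0, dev0, valid0 = brute_force_strain(u, mask_arr, spacing)
            np.testing.assert_array_equal(sf.valid, valid0)
            v = sf.valid
            np.testing.assert_allclose(sf.F[v], F0[v], atol=1e-12)
            np.testing.assert_allclose(sf.E[v], E0[v], atol=1e-12)
            np.testing.assert_allclose(sf.E_hyd[v], hyd0[v], atol=1e-12)
            np.testing.assert_allclose(sf.E_dev[v], dev0[v], atol=1e-12)

    def test_invariants_of_strain_field(self, rng):
        u = rng.normal(scale=0.05, size=(7, 7, 7, 3))
        fld = DisplacementField(u, np.eye(4))
        mask = MaskVolume(np.ones((7, 7, 7), bool), np.eye(4))
        sf = compute_strain(fld, mask)
        np.testing.assert_allclose(sf.E, np.transpose(sf.E, (0, 1, 2, 4, 3)),
                                   atol=1e-12)
        np.testing.assert_allclose(
            np.trace(sf.E_dev, axis1=-2, axis2=-1), 0.0, atol=1e-12)
        np.testing.assert_allclose(
            sf.E_hyd, np.trace(sf.E, axis1=-2, axis2=-1) / 3.0, atol=0)
        np.testing.assert_allclose(
            sf.E_dev + sf.E_hyd[..., None, None] * np.eye(3), sf.E, atol=1e-15)

    def test_rigid_motion_gives_negligible_strain(self):
        # rigid rotation + translation as a displacement field
        R = rotation_about("z", 4.0) @ rotation_about("x", -3.0)
        t = np.array([1.0, -2.0, 0.5])
        fld, mask, world = _field_from_function(
            lambda w: w @ (R - np.eye(3)).T + t, shape=(11, 11, 11))
        sf = compute_strain(fld, mask)
        interior = np.zeros(mask.shape, bool)
        interior[1:-1, 1:-1, 1:-1] = True
        assert np.abs(sf.E[interior]).max() < 1e-6

    def test_small_strain_limit_matches_symmetric_gradient(self, rng):
        A = rng.normal(scale=1e-4, size=(3, 3))
        fld, mask, _ = _field_from_function(lambda w: w @ A.T)
        sf = compute_strain(fld, mask)
        sym = 0.5 * (A + A.T)
        interior = sf.valid
        rel = np.abs(sf.E[interior] - sym) / max(np.abs(sym).max(), 1e-30)
        assert rel.max() < 1e-2


class TestPercentMaps:
    def test_scaling_and_masking(self):
        A = np.diag([0.0018, 0.0, 0.0])
        fld, mask, _ = _field_from_function(lambda w: w @ A.T)
        sf = compute_strain(fld, mask)
        maps = strain_percent_maps(sf)
        v = sf.valid
        np.testing.assert_allclose(maps["E_xx"][v],
                                   100 * sf.E[v][:, 0, 0], atol=1e-12)
        # E_xx = ((1 + 0.0018)^2 - 1)/2 = 0.0018016…, i.e. 0.18 %
        assert maps["E_xx"][v].mean() == pytest.approx(
            100 * ((1.0018) ** 2 - 1) / 2, rel=1e-9)
        zero = compute_strain(
            DisplacementField(np.zeros((9, 9, 9, 3)), np.eye(4)),
            MaskVolume(np.ones((9, 9, 9), bool), np.eye(4)))
        for arr in strain_percent_maps(zero).values():
            np.testing.assert_allclose(arr, 0.0, atol=0)
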