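import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbshift.cohortstats import (
    brain_tables,
    center_angles,
    circular_sd,
    from_spherical,
    roi_summary,
    slope_per_unit,
    spearman,
    to_spherical,
    wrap_display,
)
from pbshift.volio import DisplacementField, MaskVolume, ROIAtlas


class TestSphericalConventions:
    @pytest.mark.parametrize("vec,azimuth,elevation", [
        ((1, 0, 0), 0.0, None),     # subject's right
        ((0, 1, 0), 90.0, 0.0),     # anterior
        ((0, -1, 0), -90.0, 180.0),  # posterior
        ((-1, 0, 0), 180.0, None),  # left
        ((0, 0, 1), None, 90.0),    # superior
        ((0, 1, 1), 90.0, 45.0),
    ])
    def test_cardinal_directions(self, vec, azimuth, elevation):
        s = to_spherical(np.array(vec, float))
        if azimuth is not None:
            assert s.azimuth == pytest.approx(azimuth)
        if elevation is not None:
            assert s.elevation == pytest.approx(elevation)
        assert s.magnitude == pytest.approx(np.linalg.norm(vec))

    def test_leftward_vectors_fall_below_minus_90(self):
        # posterior-and-left vectors have azimuth in (-180, -90)
        s = to_spherical(np.array([-0.5, -0.5, 0.0]))
        assert -180 < s.azimuth < -90

    def test_zero_vector_flagged(self):
        s = to_spherical(np.zeros(3))
        assert not s.defined and s.magnitude == 0.0

    def test_wrap_display(self):
        assert wrap_display(-90.0) == pytest.approx(270.0)
        assert wrap_display(170.0) == pytest.approx(170.0)

    @given(
        st.lists(
            st.floats(-1, 1).filter(lambda x: x == 0.0 or abs(x) > 1e-6),
            min_size=3, max_size=3),
        st.floats(0.1, 5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_through_spherical(self, v, mag):
        # components are 0 or of representable size: at directions where
        # two components are infinitesimal relative to the third, the
        # (azimuth, elevation) chart is genuinely non-invertible
        v = np.asarray(v)
        if np.linalg.norm(v) < 1e-6:
            return
        s = to_spherical(v / np.linalg.norm(v) * mag)
        back = from_spherical(s.azimuth, s.elevation, s.magnitude)
        s2 = to_spherical(back)
        assert s2.magnitude == pytest.approx(s.magnitude, rel=1e-9)
        assert (s2.azimuth - s.azimuth) % 360 == pytest.approx(0, abs=1e-6) \
            or (s2.azimuth - s.azimuth) % 360 == pytest.approx(360, abs=1e-6)
        assert (s2.elevation - s.elevation) % 360 == pytest.approx(0, abs=1e-6) \
            or (s2.elevation - s.elevation) % 360 == pytest.approx(360, abs=1e-6)

    def test_center_angles_removes_wrap(self):
        a = np.array([175.0, -178.0, 179.0, -175.0])
        c = center_angles(a)
        assert c.max() - c.min() < 15.0
        np.testing.assert_allclose(np.cos(np.radians(c)), np.cos(np.radians(a)),
                                   atol=1e-12)

    def test_circular_sd_of_tight_cluster(self):
        assert circular_sd([10.0, 10.0, 10.0]) == pytest.approx(0.0, abs=1e-6)
        assert circular_sd([359.0, 1.0, 0.0]) < 2.0


def _uniform_field(vec, shape=(4, 4, 4)):
    u = np.broadcast_to(np.asarray(vec, float), shape + (3,)).copy()
    return DisplacementField(u, np.eye(4))


class TestROISummary:
    @pytest.fixture()
    def atlas(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[:2] = 1
        labels[2:] = 2
        return ROIAtlas(labels, np.eye(4), {1: "deep", 2: "cortex"})

    def test_identical_uniform_fields(self, atlas):
        fields = [_uniform_field((0, -0.2, 0)) for _ in range(3)]
        s = roi_summary(fields, atlas, "deep")
        assert s.mean.azimuth == pytest.approx(-90.0)
        assert s.mean.magnitude == pytest.approx(0.2)
        assert s.variability_mm == pytest.approx(0.0, abs=1e-12)

    def test_two_subject_variability_is_sd_of_means(self, atlas):
        fields = [_uniform_field((0, -0.1, 0)), _uniform_field((0, -0.3, 0))]
        s = roi_summary(fields, atlas, "deep")
        assert s.mean.magnitude == pytest.approx(0.2)
        assert s.variability_mm == pytest.approx(np.std([0.1, 0.3], ddof=1))

    def test_empty_roi_rejected(self, atlas):
        atlas2 = ROIAtlas(np.where(atlas.labels == 1, 0, atlas.labels),
                          np.eye(4), dict(atlas.table))
        fields = [_uniform_field((0, 1, 0))] * 2
        with pytest.raises(ValueError):
            roi_summary(fields, atlas2, "deep")


class TestBrainTables:
    def brute_force(self, stacks, mask):
        """Direct re-implementation on flat lists of voxels."""
        arr = np.stack(stacks)  # (n, X, Y, Z, 3)
        mean_field = arr.mean(axis=0)
        rows = {}
        for c, name in enumerate(["L-R", "P-A", "I-S"]):
            vals = mean_field[mask][:, c]
            rows[name] = (vals.mean(), vals.std(ddof=1),
                          arr.std(axis=0, ddof=1)[mask][:, c].mean())
        mag_mean = np.linalg.norm(mean_field, axis=-1)[mask]
        mags = np.linalg.norm(arr, axis=-1)
        rows["Magnitude"] = (mag_mean.mean(), mag_mean.std(ddof=1),
                             mags.std(axis=0, ddof=1)[mask].mean())
        return rows

    def test_identical_subjects_have_zero_variability(self):
        f = _uniform_field((-0.09, -0.2, 0.10))
        mask = MaskVolume(np.ones((4, 4, 4), bool), np.eye(4))
        t = brain_tables([f, f, f], mask)["displacement"]
        np.testing.assert_allclose(t["intersubject_variability"], 0.0,
                                   atol=1e-12)
        means = t.set_index("quantity")["mean"]
        assert means["L-R"] == pytest.approx(-0.09)
        assert means["P-A"] == pytest.approx(-0.2)
        assert means["I-S"] == pytest.approx(0.10)
        assert means["Magnitude"] == pytest.approx(
            np.linalg.norm([-0.09, -0.2, 0.10]))

    def test_matches_brute_force_on_random_cohort(self, rng):
        shape = (3, 2, 2)
        mask_arr = rng.random(shape) > 0.3
        mask_arr.flat[0] = True
        fields = [DisplacementField(rng.normal(size=shape + (3,)), np.eye(4))
                  for _ in range(3)]
        t = brain_tables(fields, MaskVolume(mask_arr, np.eye(4)))
        expected = self.brute_force([f.vectors for f in fields], mask_arr)
        for _, row in t["displacement"].iterrows():
            e = expected[row["quantity"]]
            assert row["mean"] == pytest.approx(e[0], abs=1e-12)
            assert row["sd"] == pytest.approx(e[1], abs=1e-12)
            assert row["intersubject_variability"] == pytest.approx(e[2],
                                                                    abs=1e-12)


def brute_force_spearman_p(x, y):
    """Full-permutation two-sided p via exact integer S statistics."""
    n = len(x)
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    s_obs = int(np.sum((rx - ry) ** 2))
    smax = n * (n * n - 1) // 3
    dev_obs = abs(smax - 2 * s_obs)  # |rho| proportional to |smax - 2S|
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        s = int(sum((rx[i] - perm[i]) ** 2 for i in range(n)))
        if abs(smax - 2 * s) >= dev_obs:
            count += 1
        total += 1
    return count / total


class TestSpearman:
    def test_monotone_gives_unit_correlation(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 11.0])
        r, p = spearman(x, np.exp(x))
        assert r == pytest.approx(1.0)
        r2, _ = spearman(x, -np.exp(x))
        assert r2 == pytest.approx(-1.0)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_matches_full_enumeration(self, n, rng):
        for _ in range(5):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            _, p = spearman(x, y)
            assert p == pytest.approx(brute_force_spearman_p(x, y), abs=1e-12)

    def test_exact_p_for_perfect_rank_agreement(self):
        # P(|rho| = 1) under the null = 2/n!
        x = np.arange(6.0)
        _, p = spearman(x, x * 3 + 1)
        assert p == pytest.approx(2 / math.factorial(6))

    def test_constant_input_flagged(self):
        r, p = spearman(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and np.isnan(p)

    def test_large_n_uses_approximation_consistent_with_scipy(self, rng):
        from scipy import stats

        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        r, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert r == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestSlope:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        assert slope_per_unit(x, 2 * x, per=10.0) == pytest.approx(20.0)

    def test_constant_y(self):
        x = np.array([0.0, 1.0, 2.0])
        assert slope_per_unit(x, np.ones(3), per=10.0) == pytest.approx(0.0)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError):
            slope_per_unit(np.ones(4), np.arange(4.0))
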