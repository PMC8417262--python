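"""Spherical conventions, ROI/whole-brain statistics, correlations.

Angle conventions (RAS components r=right, a=anterior, s=superior):

* azimuth — orientation in the axial plane, measured from the positive
  L-R axis (+x, subject's right): ``atan2(a, r)`` in degrees, so 0° =
  right, +90° = anterior, −90° = posterior and ±180° = left; values
  falling from −90° toward −180° are vectors progressively oriented
  toward the left.
* elevation — orientation in the sagittal projection, measured from the
  positive P-A axis (+y, anterior): ``atan2(s, a)``, so 0° = anterior,
  90° = superior, 180° = posterior; the L-R component does not affect
  elevation.

Angles are computed in (−180, 180]; :func:`wrap_display` maps to
[0, 360) for figure-style ranges. A cohort's mean direction is the
direction of the mean vector (not the mean of angles); inter-subject
variability is the across-subject standard deviation of the per-subject
summary (magnitude in mm) or the circular standard deviation (angles).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .volio import DisplacementField, MaskVolume, ROIAtlas, roi_mask


@dataclass(frozen=True)
class SphericalSummary:
    azimuth: float  # degrees in (-180, 180]; nan if undefined
    elevation: float
    magnitude: float  # mm, >= 0
    defined: bool = True


def to_spherical(v: np.ndarray) -> SphericalSummary:
    """Spherical summary of one RAS vector (see module conventions)."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite vector")
    mag = float(np.linalg.norm(v))
    if mag == 0.0:
        return SphericalSummary(np.nan, np.nan, 0.0, defined=False)
    r, a, s = v[0] + 0.0, v[1] + 0.0, v[2] + 0.0  # normalise signed zeros
    az = float(np.degrees(np.arctan2(a, r)))
    el = float(np.degrees(np.arctan2(s, a)))
    return SphericalSummary(az, el, mag)


def from_spherical(azimuth: float, elevation: float, magnitude: float) -> np.ndarray:
    """Right inverse of :func:`to_spherical` on its image.

    Solves ``azimuth = atan2(a, r)`` and ``elevation = atan2(s, a)`` for
    a direction (r, a, s): the axial radius p >= 0 and sagittal radius
    q >= 0 satisfy ``a = p sin(az) = q cos(el)``. For a vector actually
    produced by :func:`to_spherical` the two sides agree in sign; the
    degenerate purely-lateral case (sin az ~ 0, so a ~ 0) falls back to
    the (r, s) plane.
    """
    az, el = np.radians(azimuth), np.radians(elevation)

    def clean(x):  # flush sin/cos roundoff at multiples of 90 deg
        return 0.0 if abs(x) < 1e-9 else float(x)

    sa, ca = clean(np.sin(az)), clean(np.cos(az))
    se, ce = clean(np.sin(el)), clean(np.cos(el))
    if sa == 0.0:
        # anterior component vanishes to azimuth precision; keep an
        # infinitesimal a of the sign elevation demands so that both
        # angle charts reproduce (180 deg elevation needs a < 0)
        vec = np.array([ca, ce * 1e-20, se], dtype=float)
    elif ce == 0.0:
        # elevation +-90: superior component dominates any planar part
        vec = np.array([ca, sa, np.sign(se) * 1e12], dtype=float)
    else:
        q = abs(sa) / abs(ce)  # makes |a| agree between the two charts
        vec = np.array([ca, sa, q * se * np.sign(sa * ce)], dtype=float)
    n = np.linalg.norm(vec)
    return vec / n * magnitude if n > 0 else vec


def wrap_display(angle_deg: float) -> float:
    """Wrap an angle from (−180, 180] to [0, 360) for display."""
    return float(np.mod(angle_deg, 360.0))


def center_angles(angles_deg: np.ndarray) -> np.ndarray:
    """Map angles onto the continuous branch centred on their circular
    mean, so that rank/linear statistics are immune to the ±180° wrap
    (e.g. elevations straddling the posterior direction)."""
    a = np.asarray(angles_deg, dtype=float)
    rad = np.radians(a)
    mu = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
    return mu + (a - mu + 180.0) % 360.0 - 180.0


def circular_sd(angles_deg: np.ndarray) -> float:
    """Circular standard deviation in degrees (Mardia's definition)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    c, s = np.cos(a).mean(), np.sin(a).mean()
    r = np.hypot(c, s)
    r = min(max(r, 1e-300), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


# ---------------------------------------------------------------------------
# ROI and whole-brain summaries


def roi_mean_vector(field: DisplacementField, mask: MaskVolume) -> np.ndarray:
    if field.shape != mask.shape:
        raise ValueError("field and mask grids differ")
    if not mask.data.any():
        raise ValueError("empty ROI")
    return field.vectors[mask.data].mean(axis=0)


@dataclass
class ROISummary:
    roi: str
    mean: SphericalSummary  # spherical form of the cohort-mean vector
    variability_mm: float  # SD across subjects of per-subject ROI-mean |v|
    variability_azimuth: float  # circular SD across subjects, degrees
    variability_elevation: float
    per_subject_vectors: np.ndarray  # (n_subjects, 3)


def roi_summary(
    fields: list[DisplacementField], atlas: ROIAtlas, roi: str | list[str]
) -> ROISummary:
    """Cohort summary of one (possibly compound) ROI.

    Per subject the ROI-mean Cartesian vector is taken; the cohort mean
    vector is the average of subject vectors, reported in spherical
    form; magnitude variability is the SD across subjects of the
    per-subject ROI-mean magnitudes; angular variability is the circular
    SD of per-subject angles.
    """
    if len(fields) < 2:
        raise ValueError("need at least 2 subjects")
    mask = roi_mask(atlas, roi)
    vecs = np.stack([roi_mean_vector(f, mask) for f in fields])
    mean_vec = vecs.mean(axis=0)
    mags = np.linalg.norm(vecs, axis=1)
    sph = [to_spherical(v) for v in vecs]
    name = roi if isinstance(roi, str) else "+".join(roi)
    return ROISummary(
        roi=name,
        mean=to_spherical(mean_vec),
        variability_mm=float(mags.std(ddof=1)),
        variability_azimuth=circular_sd([s.azimuth for s in sph]),
        variability_elevation=circular_sd([s.elevation for s in sph]),
        per_subject_vectors=vecs,
    )


def brain_tables(
    fields: list[DisplacementField],
    brain: MaskVolume,
    strain_diagonals: list[np.ndarray] | None = None,
    strain_valid: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """Whole-brain displacement (and optionally strain) summary tables.

    Displacement rows (L-R, P-A, I-S components and magnitude): mean and
    SD over brain voxels of the across-subject mean field;
    inter-subject variability = brain-mean of the per-voxel SD across
    subjects. The strain table applies the identical construction to the
    diagonal strain components, in percent.
    """
    if len(fields) < 2:
        raise ValueError("need at least 2 subjects")
    m = brain.data
    stack = np.stack([f.vectors for f in fields])  # (n, X, Y, Z, 3)
    mean_field = stack.mean(axis=0)
    sd_across = stack.std(axis=0, ddof=1)

    rows = []
    comp_names = ["L-R", "P-A", "I-S"]
    for c, name in enumerate(comp_names):
        rows.append({
            "quantity": name,
            "mean": mean_field[m][:, c].mean(),
            "sd": mean_field[m][:, c].std(ddof=1),
            "intersubject_variability": sd_across[m][:, c].mean(),
        })
    mags = np.linalg.norm(stack, axis=-1)  # (n, X, Y, Z)
    mag_mean = np.linalg.norm(mean_field, axis=-1)
    rows.append({
        "quantity": "Magnitude",
        "mean": mag_mean[m].mean(),
        "sd": mag_mean[m].std(ddof=1),
        "intersubject_variability": mags.std(axis=0, ddof=1)[m].mean(),
    })
    out = {"displacement": pd.DataFrame(rows)}

    if strain_diagonals is not None:
        sstack = np.stack(strain_diagonals) * 100.0  # (n, X, Y, Z, 3) in %
        valid = strain_valid if strain_valid is not None else m
        smean = sstack.mean(axis=0)
        ssd = sstack.std(axis=0, ddof=1)
        srows = []
        for c, name in enumerate(comp_names):
            srows.append({
                "quantity": name,
                "mean": smean[valid][:, c].mean(),
                "sd": smean[valid][:, c].std(ddof=1),
                "intersubject_variability": ssd[valid][:, c].mean(),
            })
        out["strain"] = pd.DataFrame(srows)
    return out


# ---------------------------------------------------------------------------
# Spearman correlation with exact small-sample p


@lru_cache(maxsize=None)
def _exact_s_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of S = sum d_i^2 over all n! rank
    permutations, by dynamic programming over assigned-rank subsets.

    Returns (support, counts). Equivalent to full enumeration; feasible
    for the n <= 12 regime where it is used.
    """
    smax = n * (n * n - 1) // 3
    # dp[mask] = counts over S values for permutations of the first
    # popcount(mask) positions using exactly the ranks in mask
    from collections import defaultdict

    dp: dict[int, np.ndarray] = {0: np.zeros(smax + 1, dtype=np.int64)}
    dp[0][0] = 1
    for mask in range(1, 1 << n):
        i = bin(mask).count("1") - 1  # position being assigned (0-based)
        acc = np.zeros(smax + 1, dtype=np.int64)
        for j in range(n):
            if mask & (1 << j):
                d2 = (i - j) ** 2
                prev = dp[mask ^ (1 << j)]
                if d2 == 0:
                    acc += prev
                else:
                    acc[d2:] += prev[:-d2]
        dp[mask] = acc
        # free memory of masks that can no longer be reached
    full = dp[(1 << n) - 1]
    support = np.nonzero(full)[0]
    return support, full[support]


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    For n <= 12 and tie-free data, p is exact: the proportion of the
    full permutation null with |rho| >= |rho observed|, computed from
    the exact distribution of S = sum of squared rank differences. With
    ties (average ranks) or larger n, the t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("missing values not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= 12 and not ties:
        s_obs = int(round(np.sum((rx - ry) ** 2)))
        support, counts = _exact_s_distribution(n)
        smax = n * (n * n - 1) // 3
        # |rho| >= |rho_obs|  <=>  S <= s or S >= smax - s (null symmetric)
        s_lo = min(s_obs, smax - s_obs)
        total = counts.sum()
        p = counts[(support <= s_lo) | (support >= smax - s_lo)].sum() / total
        return rho, float(min(p, 1.0))
    return rho, float(stats.spearmanr(x, y).pvalue)


def slope_per_unit(x: np.ndarray, y: np.ndarray, per: float = 1.0) -> float:
    """OLS slope of y on x, rescaled to 'per' units of x (e.g. per 10 mm)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    slope = np.polyfit(x, y, 1)[0]
    return float(slope * per)


# ---------------------------------------------------------------------------
# cohort-level correlation grid


def correlation_analysis(cohort, brain_masks=None) -> pd.DataFrame:
    """Correlate PBS summaries with geometry and head orientation.

    Covariates: APD, MCB, prone/supine gravity elevation, brain volume.
    Responses: brain-mean-field azimuth, elevation, magnitude, and the
    lateral (L-R) component. Spearman r/p plus OLS slopes in reporting
    units (per 10 mm of diameter, per 10 degrees of gravity elevation).
    No multiple-testing correction is applied.

    ``cohort`` is a list of SubjectRecord whose ``normalized_field`` (or
    ``truth_field``), gravity vectors and APD/MCB are populated.
    """
    needed = ["apd", "mcb", "gravity_supine", "gravity_prone"]
    for rec in cohort:
        missing = [f for f in needed if getattr(rec, f, None) is None]
        if missing:
            raise ValueError(f"{rec.id}: missing covariates {missing}")

    rows = []
    covs: dict[str, np.ndarray] = {}
    resp: dict[str, np.ndarray] = {}
    az, el, mag, lat, vol_l = [], [], [], [], []
    for rec in cohort:
        fld = rec.normalized_field if rec.normalized_field is not None else rec.truth_field
        if fld is None:
            raise ValueError(f"{rec.id}: missing displacement field")
        mask = rec.brain_template if getattr(rec, "brain_template", None) is not None else rec.brain
        v = roi_mean_vector(fld, mask)
        s = to_spherical(v)
        az.append(s.azimuth)
        el.append(s.elevation)
        # magnitude = brain-mean of per-voxel |u| (the Table-2 magnitude),
        # not the norm of the mean vector
        mag.append(float(np.linalg.norm(fld.vectors[mask.data], axis=-1).mean()))
        lat.append(v[0])
        voxvol = float(np.prod(mask.spacing))
        vol_l.append(mask.data.sum() * voxvol / 1000.0)  # mL

    covs["APD"] = np.array([r.apd for r in cohort])
    covs["MCB"] = np.array([r.mcb for r in cohort])
    covs["gravity_elev_supine"] = center_angles(
        [r.gravity_supine.elevation for r in cohort])
    covs["gravity_elev_prone"] = center_angles(
        [r.gravity_prone.elevation for r in cohort])
    covs["brain_volume_mL"] = np.array(vol_l)
    resp["pbs_azimuth"] = center_angles(az)
    resp["pbs_elevation"] = center_angles(el)
    resp["pbs_magnitude"] = np.array(mag)
    resp["pbs_lateral"] = np.array(lat)

    per_units = {"APD": 10.0, "MCB": 10.0, "gravity_elev_supine": 10.0,
                 "gravity_elev_prone": 10.0, "brain_volume_mL": 100.0}
    for cname, xv in covs.items():
        for rname, yv in resp.items():
            r, p = spearman(xv, yv)
            try:
                slope = slope_per_unit(xv, yv, per_units[cname])
            except ValueError:
                slope = np.nan
            rows.append({
                "covariate": cname, "response": rname,
                "spearman_r": r, "p": p,
                "slope": slope, "slope_per": per_units[cname],
            })
    return pd.DataFrame(rows)
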