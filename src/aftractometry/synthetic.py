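"""Synthetic phantoms for along-tract DTI analysis.

Real inputs to this kind of study — probabilistic tractography density
maps, DTI parameter maps, language fMRI Z-maps — come from subject MRI
that is rarely shareable.  This module builds phantoms with known ground
truth so that every downstream stage (spectral parameterization,
tractometry, normative modelling, laterality, statistics) is testable:

* a curved tube-shaped "tract" density map following an arcuate-
  fasciculus-like arch from frontal to temporal positions, with the true
  arc-length fraction of every in-tube voxel recorded;
* healthy-control cohorts whose FA/AD/RD maps vary smoothly around
  realistic baselines (MD is derived as (AD + 2 RD)/3 so maps are always
  tensor-consistent);
* patient volumes with focal "lesions" that raise MD/RD and depress
  FA/AD on a known set of tract segments;
* lateralized activation Z-maps realizing a requested voxel-count
  laterality index.

All randomness flows from explicit seeds; identical specs produce
bit-identical volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .volume import ScalarVolume, center_ras_affine

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "PatientSpec",
    "Centerline",
    "default_af_control_points",
    "default_lesion_deltas",
    "make_centerline",
    "rasterize_tube",
    "truth_segment_labels",
    "make_dti_cohort",
    "make_zmap",
    "simulate_hc_profiles",
    "simulate_patient_profile",
]

DTI_PARAMETERS = ("FA", "MD", "AD", "RD")

#: fraction of between-subject variance carried by a global per-subject
#: offset (the rest is smoothed spatial noise); total per-voxel SD
#: equals the declared subject_sd either way.
_OFFSET_VARIANCE_SHARE = 0.5

_DENSITY_PEAK = 100.0


class PhantomSpecError(ValueError):
    """Invalid phantom specification."""


def default_af_control_points(hemisphere: str = "L") -> list[tuple[float, float, float]]:
    """Control points (mm) of a C-shaped arcuate-like arch in one sagittal plane.

    The curve starts anteriorly/superiorly (frontal terminations), arches
    over a Sylvian-fissure-like gap and descends to the temporal end.
    ``hemisphere='R'`` mirrors x.
    """
    x = -30.0 if hemisphere.upper() == "L" else 30.0
    pts = [
        (x, 44.0, 2.0),    # frontal end
        (x, 34.0, 18.0),
        (x, 14.0, 28.0),   # top of the arch
        (x, -12.0, 26.0),
        (x, -28.0, 10.0),
        (x, -34.0, -12.0),
        (x, -28.0, -28.0),  # temporal end
    ]
    return pts


def default_lesion_deltas(grade: str = "HG") -> dict[str, float]:
    """Additive lesion offsets per DTI parameter (diffusivities in 1e-3 mm^2/s).

    High-grade defaults sit at the extreme of the patient-vs-control
    contrast observed for along-tract medians in infiltrated arcuate
    segments (axial diffusivity up ~0.11, radial up ~0.14, FA down
    ~0.07); the MD offset is derived tensor-consistently as
    (dAD + 2 dRD)/3.  Low-grade lesions use half that amplitude.
    """
    d_ad, d_rd, d_fa = 0.11, 0.14, -0.07
    if grade.upper() == "LG":
        d_ad, d_rd, d_fa = d_ad / 2, d_rd / 2, d_fa / 2
    elif grade.upper() != "HG":
        raise ValueError(f"grade must be 'LG' or 'HG', got {grade!r}")
    return {"FA": d_fa, "AD": d_ad, "RD": d_rd, "MD": (d_ad + 2 * d_rd) / 3.0}


@dataclass
class PhantomSpec:
    """Geometry + generative parameters of the synthetic tract phantom.

    Diffusivities are in 1e-3 mm^2/s throughout; FA is dimensionless.
    Baselines default to healthy-control along-tract medians typical of
    the arcuate fasciculus (FA 0.43, AD 0.88, MD 0.58, RD 0.44).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    curve_control_points: list[tuple[float, float, float]] = field(
        default_factory=default_af_control_points
    )
    tube_radius_mm: float = 4.0
    density_falloff: float = 2.0
    dti_baselines: dict[str, float] = field(
        default_factory=lambda: {"FA": 0.43, "AD": 0.88, "RD": 0.44, "MD": 0.5866666666666667}
    )
    subject_sd: dict[str, float] = field(
        default_factory=lambda: {"FA": 0.02, "AD": 0.04, "RD": 0.04, "MD": 0.03}
    )
    n_segments: int = 15
    lesion_segments: frozenset[int] = frozenset()
    lesion_deltas: dict[str, float] = field(default_factory=default_lesion_deltas)
    noise_smoothing_voxels: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise PhantomSpecError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if self.voxel_size_mm <= 0:
            raise PhantomSpecError("voxel_size_mm must be positive")
        if self.tube_radius_mm <= 0 or self.density_falloff <= 0:
            raise PhantomSpecError("tube_radius_mm and density_falloff must be positive")
        b = self.dti_baselines
        missing = set(DTI_PARAMETERS) - set(b)
        if "MD" in missing and {"AD", "RD"} <= set(b):
            b["MD"] = (b["AD"] + 2 * b["RD"]) / 3.0
            missing.discard("MD")
        if missing:
            raise PhantomSpecError(f"dti_baselines missing {sorted(missing)}")
        if not (0 < b["FA"] < 1):
            raise PhantomSpecError(f"baseline FA must be in (0,1), got {b['FA']}")
        if not (b["AD"] >= b["MD"] >= b["RD"] > 0):
            raise PhantomSpecError(
                "baselines must satisfy AD >= MD >= RD > 0, got "
                f"AD={b['AD']}, MD={b['MD']}, RD={b['RD']}"
            )
        self.lesion_segments = frozenset(int(s) for s in self.lesion_segments)
        bad = [s for s in self.lesion_segments if not 1 <= s <= self.n_segments]
        if bad:
            raise PhantomSpecError(
                f"lesion_segments {bad} outside 1..{self.n_segments}"
            )

    @property
    def affine(self) -> np.ndarray:
        return center_ras_affine(self.grid_shape, self.voxel_size_mm)


@dataclass
class PatientSpec:
    """One synthetic patient: group label, hemisphere, lesion placement."""

    subject_id: str
    group: str  # "LG" | "HG"
    hemisphere: str = "L"
    lesion_segments: frozenset[int] = frozenset()
    lesion_deltas: dict[str, float] = field(default_factory=default_lesion_deltas)


@dataclass
class Centerline:
    """Densely sampled tract centerline in mm."""

    points: np.ndarray       # (n, 3)
    arc_length: np.ndarray   # (n,) cumulative, arc_length[0] == 0

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    @property
    def arc_fraction(self) -> np.ndarray:
        return self.arc_length / self.total_length


def make_centerline(control_points, n_samples: int = 1024) -> Centerline:
    """Interpolate ordered control points with a chord-length cubic spline.

    The first control point is the t=0 (frontal) end.  Raises
    :class:`PhantomSpecError` for fewer than 3 control points, duplicate
    consecutive points, or n_samples < 10.
    """
    pts = np.asarray(control_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise PhantomSpecError(
            f"need >= 3 control points of dimension 3, got shape {pts.shape}"
        )
    if n_samples < 10:
        raise PhantomSpecError(f"n_samples must be >= 10, got {n_samples}")
    chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(chords == 0):
        raise PhantomSpecError("duplicate consecutive control points")
    u = np.concatenate([[0.0], np.cumsum(chords)])
    spline = CubicSpline(u, pts, axis=0)
    samples = spline(np.linspace(0.0, u[-1], n_samples))
    seglen = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    if np.any(np.diff(arc) <= 0):
        raise PhantomSpecError("degenerate centerline: arc length not strictly increasing")
    return Centerline(points=samples, arc_length=arc)


def rasterize_tube(curve: Centerline, spec: PhantomSpec) -> tuple[ScalarVolume, ScalarVolume]:
    """Rasterize a Gaussian-profile tube around the centerline.

    Returns ``(density, t_truth)``: voxel density is
    ``D0 * exp(-d^2 / (2 falloff^2))`` for distance ``d`` from the
    centerline, exactly zero beyond ``tube_radius_mm``; ``t_truth`` holds
    the arc-length fraction of each in-tube voxel's nearest centerline
    sample (NaN outside the tube).
    """
    affine = spec.affine
    vol = ScalarVolume(np.zeros(spec.grid_shape, dtype=float), affine)
    lo = vol.voxel_to_mm([[0, 0, 0]])[0] - spec.voxel_size_mm / 2
    hi = vol.voxel_to_mm([np.asarray(spec.grid_shape) - 1])[0] + spec.voxel_size_mm / 2
    cmin = curve.points.min(axis=0) - spec.tube_radius_mm
    cmax = curve.points.max(axis=0) + spec.tube_radius_mm
    if np.any(cmin < lo) or np.any(cmax > hi):
        raise PhantomSpecError(
            "tube exits the grid: tube extent "
            f"[{np.round(cmin, 1)}, {np.round(cmax, 1)}] mm vs grid "
            f"[{np.round(lo, 1)}, {np.round(hi, 1)}] mm"
        )
    coords = vol.grid_coords_mm().reshape(-1, 3)
    dist, nearest = cKDTree(curve.points).query(coords, workers=-1)
    inside = dist <= spec.tube_radius_mm
    density = np.zeros(coords.shape[0])
    density[inside] = _DENSITY_PEAK * np.exp(
        -(dist[inside] ** 2) / (2.0 * spec.density_falloff**2)
    )
    t_truth = np.full(coords.shape[0], np.nan)
    t_truth[inside] = curve.arc_fraction[nearest[inside]]
    return (
        ScalarVolume(density.reshape(spec.grid_shape), affine),
        ScalarVolume(t_truth.reshape(spec.grid_shape), affine),
    )


def truth_segment_labels(t_truth: ScalarVolume, n_segments: int) -> ScalarVolume:
    """Ground-truth segment labels 1..K from the arc-fraction volume (0 outside)."""
    t = t_truth.data
    labels = np.zeros(t.shape, dtype=np.int32)
    inside = np.isfinite(t)
    k = np.floor(t[inside] * n_segments).astype(np.int32) + 1
    labels[inside] = np.clip(k, 1, n_segments)
    return ScalarVolume(labels, t_truth.affine)


# --------------------------------------------------------------------- DTI

def _smooth_unit_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Smoothed white Gaussian noise renormalized to unit per-voxel SD."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = f.std()
    if sd == 0:  # pathological tiny grids
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _subject_maps(
    spec: PhantomSpec, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw FA/AD/RD fields around the baselines; derive MD = (AD + 2 RD)/3."""
    maps: dict[str, np.ndarray] = {}
    for p in ("FA", "AD", "RD"):
        sd = spec.subject_sd[p]
        offset = rng.normal(0.0, sd * np.sqrt(_OFFSET_VARIANCE_SHARE))
        noise = sd * np.sqrt(1 - _OFFSET_VARIANCE_SHARE) * _smooth_unit_field(
            rng, spec.grid_shape, spec.noise_smoothing_voxels
        )
        maps[p] = spec.dti_baselines[p] + offset + noise
    maps["MD"] = (maps["AD"] + 2.0 * maps["RD"]) / 3.0
    return maps


def _apply_lesion(
    maps: dict[str, np.ndarray],
    lesion_mask: np.ndarray,
    deltas: dict[str, float],
    subject_id: str,
) -> None:
    for p in DTI_PARAMETERS:
        delta = deltas.get(p, 0.0)
        if delta == 0.0:
            continue
        maps[p][lesion_mask] += delta
        if p == "FA":
            bad = (maps[p] <= 0) | (maps[p] >= 1)
        else:
            bad = maps[p] <= 0
        if bad.any():
            logger.warning(
                "%s: lesion drove %d %s voxels out of range; clamped",
                subject_id, int(bad.sum()), p,
            )
            if p == "FA":
                np.clip(maps[p], 1e-3, 1 - 1e-3, out=maps[p])
            else:
                np.clip(maps[p], 1e-4, None, out=maps[p])


def make_dti_cohort(
    spec: PhantomSpec,
    n_hc: int,
    patients: list[PatientSpec] | None = None,
    out_dir=None,
):
    """Generate a cohort of DTI parameter maps with a ground-truth table.

    Healthy controls are baseline + per-subject offset + smooth spatial
    noise; patients additionally receive their lesion deltas on voxels
    whose ground-truth segment lies in their ``lesion_segments``.

    Returns ``(volumes, truth)`` where ``volumes`` maps subject_id ->
    {parameter -> ScalarVolume} and ``truth`` is a tidy DataFrame
    (subject_id, group, hemisphere, parameter, abnormal_segments, seed).
    With ``out_dir`` set, volumes are also written as NIfTI
    (``<subject>_<param>.nii.gz``) plus ``truth.tsv``.
    """
    if n_hc < 2:
        raise PhantomSpecError(f"need at least 2 healthy controls, got {n_hc}")
    patients = list(patients or [])
    curve = make_centerline(spec.curve_control_points)
    _, t_truth = rasterize_tube(curve, spec)
    labels = truth_segment_labels(t_truth, spec.n_segments).data

    subjects: list[tuple[str, str, str, frozenset[int], dict[str, float]]] = [
        (f"HC{i + 1:03d}", "HC", "L", frozenset(), {}) for i in range(n_hc)
    ]
    for ps in patients:
        segs = ps.lesion_segments or spec.lesion_segments
        subjects.append((ps.subject_id, ps.group, ps.hemisphere, frozenset(segs), ps.lesion_deltas))

    seeds = np.random.SeedSequence(spec.rng_seed).spawn(len(subjects))
    volumes: dict[str, dict[str, ScalarVolume]] = {}
    rows = []
    for (sid, group, hemi, segs, deltas), ss in zip(subjects, seeds):
        rng = np.random.default_rng(ss)
        maps = _subject_maps(spec, rng)
        if segs:
            lesion_mask = np.isin(labels, sorted(segs))
            _apply_lesion(maps, lesion_mask, deltas, sid)
        volumes[sid] = {p: ScalarVolume(maps[p], spec.affine) for p in DTI_PARAMETERS}
        for p in DTI_PARAMETERS:
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "hemisphere": hemi,
                    "parameter": p,
                    "abnormal_segments": ",".join(str(s) for s in sorted(segs))
                    if (segs and deltas.get(p, 0.0) != 0.0)
                    else "",
                    "seed": spec.rng_seed,
                }
            )
    truth = pd.DataFrame(rows)
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, pm in volumes.items():
            for p, v in pm.items():
                ScalarVolume(pm[p].data.astype(np.float32), v.affine).save(
                    out / f"{sid}_{p}.nii.gz"
                )
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return volumes, truth


# --------------------------------------------------------------------- fMRI

def make_zmap(
    left_mask: ScalarVolume,
    right_mask: ScalarVolume,
    target_li: float,
    z_active: float = 3.1,
    rng=None,
    n_total: int | None = None,
    tol: float = 0.05,
) -> ScalarVolume:
    """Z-map whose suprathreshold voxel counts realize a target laterality index.

    Suprathreshold voxels (z > ``z_active``) are placed inside the paired
    lobar masks so the realized (L - R)/(L + R) matches ``target_li`` up
    to integer rounding; everywhere else z stays strictly below the
    threshold.  Raises if the masks are too small to realize the target
    within ``tol``.
    """
    if not -1.0 <= target_li <= 1.0:
        raise ValueError(f"target_li must be in [-1, 1], got {target_li}")
    if not left_mask.same_grid(right_mask):
        raise ValueError("left and right masks must share a grid")
    lm = left_mask.data.astype(bool)
    rm = right_mask.data.astype(bool)
    if np.any(lm & rm):
        raise ValueError("left/right lobar masks must be disjoint")
    rng = np.random.default_rng(rng)
    nl_max, nr_max = int(lm.sum()), int(rm.sum())

    wl, wr = (1 + target_li) / 2.0, (1 - target_li) / 2.0
    if n_total is None:
        caps = []
        if wl > 0:
            caps.append(nl_max / wl)
        if wr > 0:
            caps.append(nr_max / wr)
        n_total = int(min(caps)) if caps else 0
    n_left = int(round(n_total * wl))
    n_right = n_total - n_left
    if n_left > nl_max or n_right > nr_max or n_total <= 0:
        raise ValueError(
            f"masks too small ({nl_max} L / {nr_max} R voxels) to place "
            f"{n_left}+{n_right} suprathreshold voxels"
        )
    realized = (n_left - n_right) / (n_left + n_right)
    if abs(realized - target_li) > tol:
        raise ValueError(
            f"cannot realize LI {target_li:+.3f} within +/-{tol} "
            f"(closest achievable {realized:+.3f} with masks of "
            f"{nl_max}/{nr_max} voxels)"
        )

    z = rng.normal(0.0, 1.0, size=lm.shape)
    np.clip(z, None, z_active - 0.05, out=z)  # background strictly subthreshold
    for mask, n in ((lm, n_left), (rm, n_right)):
        idx = np.flatnonzero(mask.ravel())
        chosen = rng.choice(idx, size=n, replace=False)
        flat = z.ravel()
        flat[chosen] = z_active + 0.1 + rng.exponential(1.0, size=n)
        z = flat.reshape(lm.shape)
    return ScalarVolume(z, left_mask.affine)


# -------------------------------------------------- profile-level simulators

def simulate_hc_profiles(
    n_subjects: int,
    n_segments: int = 15,
    baseline: float = 0.58,
    subject_sd: float = 0.03,
    offset_share: float = _OFFSET_VARIANCE_SHARE,
    rng=None,
) -> pd.DataFrame:
    """Gaussian segment-median profiles for a healthy cohort.

    The generative model mirrors the volumetric phantom at the profile
    level: value(s, k) = baseline + offset_s + eps_{s,k}, with the
    variance split between the shared subject offset and independent
    per-segment noise so the marginal SD equals ``subject_sd``.
    Rows are subjects (HC001..), columns segments 1..K.
    """
    rng = np.random.default_rng(rng)
    off = rng.normal(0.0, subject_sd * np.sqrt(offset_share), size=(n_subjects, 1))
    eps = rng.normal(
        0.0, subject_sd * np.sqrt(1 - offset_share), size=(n_subjects, n_segments)
    )
    return pd.DataFrame(
        baseline + off + eps,
        index=[f"HC{i + 1:03d}" for i in range(n_subjects)],
        columns=pd.RangeIndex(1, n_segments + 1, name="segment"),
    )


def simulate_patient_profile(
    lesion_segments,
    lesion_delta: float,
    n_segments: int = 15,
    baseline: float = 0.58,
    subject_sd: float = 0.03,
    offset_share: float = _OFFSET_VARIANCE_SHARE,
    rng=None,
) -> np.ndarray:
    """One patient profile: the HC generative model plus a focal lesion offset."""
    rng = np.random.default_rng(rng)
    vals = (
        baseline
        + rng.normal(0.0, subject_sd * np.sqrt(offset_share))
        + rng.normal(0.0, subject_sd * np.sqrt(1 - offset_share), size=n_segments)
    )
    for s in lesion_segments:
        if not 1 <= s <= n_segments:
            raise ValueError(f"lesion segment {s} outside 1..{n_segments}")
        vals[s - 1] += lesion_delta
    return vals
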