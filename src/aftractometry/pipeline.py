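"""End-to-end pipeline: simulate -> parameterize -> profile -> normative ->
classify -> laterality -> compare, with a run manifest.

Every tunable lives in :class:`RunConfig` (loadable from YAML); a run
directory holds TSV stage outputs plus a JSON manifest recording the
config hash, seeds, library versions and stage wall-times, so two runs
with the same config are byte-identical on the TSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import GROUP_COMPARISON_MEASURES
from .laterality import compute_laterality
from .normative import (
    NormativeRangeModel,
    classify_segments,
    summarize_subject,
)
from .stats import correlate_with_li, group_compare
from .synthetic import (
    DTI_PARAMETERS,
    PatientSpec,
    PhantomSpec,
    default_af_control_points,
    default_lesion_deltas,
    make_centerline,
    make_dti_cohort,
    make_zmap,
    rasterize_tube,
)
from .tract import TractModel
from .tractometry import profile_matrix, profiles_to_frame, segment_medians
from .volume import ScalarVolume, center_ras_affine, make_box_roi

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_report", "default_roi_boxes"]

#: group-level fMRI laterality targets per lobe (leftward > 0): low-grade
#: patients stay left-dominant, high-grade show a rightward parietal shift.
GROUP_LI_TARGETS = {
    "LG": {"frontal": 0.30, "parietal": 0.37, "temporal": 0.36},
    "HG": {"frontal": 0.02, "parietal": -0.18, "temporal": 0.33},
}

_LG_LESIONS = [frozenset(), frozenset({7}), frozenset({7, 8}), frozenset({9, 10})]
_HG_LESIONS = [
    frozenset(range(4, 13)),
    frozenset(range(3, 13)),
    frozenset(range(5, 13)),
    frozenset(range(4, 12)),
    frozenset(range(2, 14)),
]


@dataclass
class RunConfig:
    """Single source of truth for every pipeline tunable."""

    seed: int = 0
    # cohort
    n_hc: int = 32
    n_lg: int = 4
    n_hg: int = 5
    # phantom geometry
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    tube_radius_mm: float = 4.0
    density_falloff: float = 2.0
    # parameterization
    n_segments: int = 15
    density_fraction: float = 0.10
    connectivity: int = 26
    anchor: str = "frontal"
    y_max: float | None = None
    z_min: float | None = None
    core_units: str = "mm"
    # laterality / statistics
    z_thresh: float = 3.1
    fdr: float = 0.1
    li_jitter: float = 0.10
    # classification side (tumor-ipsilateral by default)
    patient_hemisphere: str = "L"
    # output
    write_volumes: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_roi_boxes(
    shape: tuple[int, int, int], affine: np.ndarray
) -> dict[str, tuple[ScalarVolume, ScalarVolume]]:
    """Mirror-symmetric lobar ROI boxes: {lobe: (left mask, right mask)}.

    Simple rectangular stand-ins for atlas language ROIs, placed where
    the frontal, parietal and temporal language areas sit in a
    grid-centered RAS frame (left hemisphere is x < 0).
    """
    spans = {
        "frontal": ((18.0, 40.0), (20.0, 50.0), (-10.0, 20.0)),
        "parietal": ((18.0, 40.0), (-45.0, -15.0), (20.0, 45.0)),
        "temporal": ((18.0, 40.0), (-40.0, 0.0), (-35.0, -5.0)),
    }
    out = {}
    for lobe, (xr, yr, zr) in spans.items():
        left = make_box_roi(shape, affine, (-xr[1], -xr[0]), yr, zr)
        right = make_box_roi(shape, affine, xr, yr, zr)
        out[lobe] = (left, right)
    return out


def _patient_specs(config: RunConfig) -> list[PatientSpec]:
    patients = []
    for i in range(config.n_lg):
        patients.append(
            PatientSpec(
                subject_id=f"LG{i + 1:02d}",
                group="LG",
                hemisphere=config.patient_hemisphere,
                lesion_segments=_LG_LESIONS[i % len(_LG_LESIONS)],
                lesion_deltas=default_lesion_deltas("LG"),
            )
        )
    for i in range(config.n_hg):
        patients.append(
            PatientSpec(
                subject_id=f"HG{i + 1:02d}",
                group="HG",
                hemisphere=config.patient_hemisphere,
                lesion_segments=_HG_LESIONS[i % len(_HG_LESIONS)],
                lesion_deltas=default_lesion_deltas("HG"),
            )
        )
    return patients


def _phantom_spec(config: RunConfig, hemisphere: str) -> PhantomSpec:
    return PhantomSpec(
        grid_shape=config.grid_shape,
        voxel_size_mm=config.voxel_size_mm,
        curve_control_points=default_af_control_points(hemisphere),
        tube_radius_mm=config.tube_radius_mm,
        density_falloff=config.density_falloff,
        n_segments=config.n_segments,
        rng_seed=config.seed,
    )


def run_pipeline(config: RunConfig, out_dir) -> dict[str, pd.DataFrame]:
    """Run every stage, writing TSV outputs and a manifest to ``out_dir``.

    Returns the stage tables: profiles, normative_model, subject_metrics,
    laterality, comparison, correlations.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    tables: dict[str, pd.DataFrame] = {}

    def _stage(name):
        logger.info("stage: %s", name)
        return time.perf_counter()

    def _done(name, t0):
        timings[name] = round(time.perf_counter() - t0, 3)

    # ------------------------------------------------------------ simulate
    t0 = _stage("simulate")
    spec_l = _phantom_spec(config, "L")
    spec_r = _phantom_spec(config, "R")
    patients = _patient_specs(config)
    try:
        volumes, truth = make_dti_cohort(spec_l, config.n_hc, patients)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    _done("simulate", t0)

    # -------------------------------------------------------- parameterize
    t0 = _stage("parameterize")
    params = {}
    for hemi, spec in (("L", spec_l), ("R", spec_r)):
        curve = make_centerline(spec.curve_control_points)
        density, _ = rasterize_tube(curve, spec)
        fit = TractModel(
            density,
            fraction=config.density_fraction,
            connectivity=config.connectivity,
            n_segments=config.n_segments,
            anchor=config.anchor,
            y_max=config.y_max,
            z_min=config.z_min,
            core_units=config.core_units,
        ).fit()
        params[hemi] = fit
        if config.write_volumes:
            density.save(out / f"density_{hemi}.nii.gz")
            fit.t_volume().save(out / f"t_{hemi}.nii.gz")
            fit.label_volume().save(out / f"labels_{hemi}.nii.gz")
    _done("parameterize", t0)

    # ------------------------------------------------------------- profile
    t0 = _stage("profile")
    groups = truth.drop_duplicates("subject_id").set_index("subject_id")["group"]
    profiles = []
    by_key = {}
    for sid, maps in volumes.items():
        for hemi, fit in params.items():
            labels = fit.label_volume()
            for p in DTI_PARAMETERS:
                prof = segment_medians(
                    maps[p], labels, config.n_segments,
                    subject_id=sid, hemisphere=hemi, parameter=p,
                )
                profiles.append(prof)
                by_key[(sid, hemi, p)] = prof
    prof_frame = profiles_to_frame(profiles)
    prof_frame.insert(1, "group", prof_frame["subject_id"].map(groups))
    prof_frame.to_csv(out / "profiles.tsv", sep="\t", index=False, float_format="%.6g")
    tables["profiles"] = prof_frame
    _done("profile", t0)

    # ----------------------------------------------------------- normative
    t0 = _stage("normative")
    hc_ids = sorted(groups[groups == "HC"].index)
    norm_results = {}
    norm_frames = []
    for hemi in params:
        for p in DTI_PARAMETERS:
            mat = profile_matrix([by_key[(s, hemi, p)] for s in hc_ids])
            res = NormativeRangeModel(mat, parameter=p, hemisphere=hemi).fit()
            norm_results[(hemi, p)] = res
            norm_frames.append(res.to_frame())
    norm_frame = pd.concat(norm_frames, ignore_index=True)
    norm_frame.to_csv(out / "normative_model.tsv", sep="\t", index=False, float_format="%.6g")
    tables["normative_model"] = norm_frame
    _done("normative", t0)

    # ------------------------------------------------------------ classify
    t0 = _stage("classify")
    hemi = config.patient_hemisphere
    voxel_vol_cm3 = (config.voxel_size_mm / 10.0) ** 3
    metric_rows = []
    for ps in patients:
        flags = {}
        profs = {}
        for p in DTI_PARAMETERS:
            prof = by_key[(ps.subject_id, hemi, p)]
            profs[p] = prof
            flags[p] = classify_segments(prof, norm_results[(hemi, p)])
        metrics = summarize_subject(ps.subject_id, ps.group, flags, profs)
        row = metrics.as_row()
        lesion_voxels = int(
            np.isin(params[hemi].label_volume().data, sorted(ps.lesion_segments)).sum()
        ) if ps.lesion_segments else 0
        row["Tumor volume"] = lesion_voxels * voxel_vol_cm3
        metric_rows.append(row)
    metrics_frame = pd.DataFrame(metric_rows)
    _done("classify", t0)

    # ----------------------------------------------------------- laterality
    t0 = _stage("laterality")
    affine = center_ras_affine(config.grid_shape, config.voxel_size_mm)
    rois = default_roi_boxes(config.grid_shape, affine)
    li_seed = np.random.SeedSequence([config.seed, 0xF1])
    li_rows = []
    for ps, ss in zip(patients, li_seed.spawn(len(patients))):
        rng = np.random.default_rng(ss)
        targets = GROUP_LI_TARGETS[ps.group]
        for lobe in sorted(rois):
            target = float(
                np.clip(targets[lobe] + rng.uniform(-config.li_jitter, config.li_jitter), -1, 1)
            )
            zmap = make_zmap(*rois[lobe], target_li=target, z_active=config.z_thresh, rng=rng)
            res = compute_laterality(zmap, {lobe: rois[lobe]}, z_thresh=config.z_thresh)
            res.insert(0, "subject_id", ps.subject_id)
            res["target_li"] = target
            li_rows.append(res)
    li_frame = pd.concat(li_rows, ignore_index=True)
    li_frame.to_csv(out / "laterality.tsv", sep="\t", index=False, float_format="%.6g")
    tables["laterality"] = li_frame

    li_wide = li_frame.pivot(index="subject_id", columns="lobe", values="li")
    for lobe in ("frontal", "parietal", "temporal"):
        metrics_frame[f"LI fMRI {lobe}"] = metrics_frame["subject_id"].map(li_wide[lobe])
    metrics_frame = metrics_frame.sort_values("subject_id").reset_index(drop=True)
    metrics_frame.to_csv(out / "subject_metrics.tsv", sep="\t", index=False, float_format="%.6g")
    tables["subject_metrics"] = metrics_frame
    _done("laterality", t0)

    # -------------------------------------------------------------- compare
    t0 = _stage("compare")
    comparison = pd.DataFrame()
    correlations = pd.DataFrame()
    if config.n_lg >= 1 and config.n_hg >= 1:
        comparison = group_compare(
            metrics_frame, "group", ("LG", "HG"), GROUP_COMPARISON_MEASURES, fdr=config.fdr
        )
        comparison.to_csv(out / "comparison.tsv", sep="\t", index=False, float_format="%.6g")
        dti_measures = [
            m
            for m in GROUP_COMPARISON_MEASURES
            if m.startswith(("FA", "AD", "MD", "RD", "Median"))
        ]
        sig = comparison.set_index("measure").loc[dti_measures]
        chosen = list(sig.index[sig["significant"]]) or dti_measures
        if config.n_lg + config.n_hg >= 3:
            correlations = correlate_with_li(
                metrics_frame.set_index("subject_id"),
                li_wide,
                chosen,
                [f for f in li_wide.columns],
                fdr=config.fdr,
                method="auto",
            )
        else:
            logger.warning("fewer than 3 patients; skipping correlations")
            correlations = pd.DataFrame(
                columns=["measure", "li", "rho", "p", "method", "q", "significant"]
            )
        correlations.to_csv(out / "correlations.tsv", sep="\t", index=False, float_format="%.6g")
    tables["comparison"] = comparison
    tables["correlations"] = correlations
    _done("compare", t0)

    # -------------------------------------------------------------- manifest
    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seconds": timings,
        "library_versions": _library_versions(),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return tables


def _library_versions() -> dict[str, str]:
    import nibabel
    import scipy

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "nibabel": nibabel.__version__,
    }


def make_report(run_dir, out_subdir: str = "report") -> list[Path]:
    """Along-tract profile plots with the shaded normative band, per
    parameter and hemisphere, plus a rendered comparison table.

    Returns the list of files written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    rep = run / out_subdir
    rep.mkdir(exist_ok=True)
    profiles = pd.read_csv(run / "profiles.tsv", sep="\t")
    model = pd.read_csv(run / "normative_model.tsv", sep="\t")
    written = []
    for (hemi, p), band in model.groupby(["hemisphere", "parameter"]):
        band = band.sort_values("segment")
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.fill_between(
            band["segment"], band["lo"], band["hi"],
            alpha=0.25, color="tab:blue", label="HC normative range (2.5–97.5 pct)",
        )
        ax.plot(band["segment"], band["median"], color="tab:blue", lw=2, label="HC median")
        sub = profiles[(profiles["hemisphere"] == hemi) & (profiles["parameter"] == p)]
        styles = {"LG": ("tab:green", "--"), "HG": ("tab:orange", "-.")}
        seen = set()
        for sid, g in sub[sub["group"] != "HC"].groupby("subject_id"):
            color, ls = styles.get(g["group"].iloc[0], ("grey", ":"))
            label = g["group"].iloc[0] if g["group"].iloc[0] not in seen else None
            seen.add(g["group"].iloc[0])
            ax.plot(g["segment"], g["median"], color=color, ls=ls, lw=1.2, label=label)
        ax.set_xlabel("AF segment (frontal → temporal)")
        unit = "" if p == "FA" else " [$10^{-3}$ mm$^2$/s]"
        ax.set_ylabel(f"{p}{unit}")
        ax.set_title(f"{p}, {hemi} arcuate fasciculus")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = rep / f"profile_{p}_{hemi}.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    comp_path = run / "comparison.tsv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path, sep="\t")
        md = rep / "comparison.md"
        md.write_text(comp.round(3).to_markdown(index=False) + "\n")
        written.append(md)
    return written
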