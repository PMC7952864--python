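"""Per-segment median DTI profiles along a parameterized tract."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import ScalarVolume

logger = logging.getLogger(__name__)

__all__ = ["SegmentProfile", "segment_medians", "profile_matrix", "profiles_to_frame"]


@dataclass
class SegmentProfile:
    """K segment medians of one DTI parameter for one subject/hemisphere.

    Diffusivities are in 1e-3 mm^2/s, FA dimensionless.  A value is NaN
    only when its segment contains no finite voxel.
    """

    subject_id: str
    hemisphere: str
    parameter: str
    values: np.ndarray    # (K,) medians, NaN where empty
    n_voxels: np.ndarray  # (K,) finite-voxel counts

    @property
    def n_segments(self) -> int:
        return len(self.values)

    def median_across_segments(self) -> float:
        return float(np.nanmedian(self.values))


def segment_medians(
    dti_map: ScalarVolume,
    labels: ScalarVolume,
    n_segments: int,
    subject_id: str = "",
    hemisphere: str = "L",
    parameter: str = "",
) -> SegmentProfile:
    """Median of the map over each segment's voxels, ignoring non-finite voxels.

    The median (not the mean) keeps single hot voxels — registration
    artifacts, partial-volume CSF — from dragging a whole segment.
    Non-finite voxels are excluded rather than propagated because
    registration padding produces NaN borders in real data.
    """
    if not dti_map.same_grid(labels):
        raise ValueError("DTI map and label volume are not on the same grid")
    lab = np.asarray(labels.data).astype(np.int64)
    vals = np.asarray(dti_map.data, dtype=float)
    medians = np.full(n_segments, np.nan)
    counts = np.zeros(n_segments, dtype=int)
    for k in range(1, n_segments + 1):
        v = vals[lab == k]
        v = v[np.isfinite(v)]
        counts[k - 1] = v.size
        if v.size:
            medians[k - 1] = np.median(v)
        else:
            logger.warning("segment %d of %s/%s is empty", k, subject_id, parameter)
    return SegmentProfile(
        subject_id=subject_id,
        hemisphere=hemisphere,
        parameter=parameter,
        values=medians,
        n_voxels=counts,
    )


def profile_matrix(profiles: list[SegmentProfile]) -> pd.DataFrame:
    """Stack subject profiles into a (subjects x segments) table.

    All profiles must share K; rows are sorted by subject id and columns
    run 1..K, so the table is deterministic regardless of input order.
    Missing segments appear as NaN.
    """
    if not profiles:
        raise ValueError("no profiles given")
    ks = {p.n_segments for p in profiles}
    if len(ks) > 1:
        raise ValueError(f"profiles have mixed segment counts: {sorted(ks)}")
    k = ks.pop()
    rows = {p.subject_id: p.values for p in sorted(profiles, key=lambda p: p.subject_id)}
    return pd.DataFrame.from_dict(rows, orient="index", dtype=float).set_axis(
        pd.RangeIndex(1, k + 1, name="segment"), axis=1
    )


def profiles_to_frame(profiles: list[SegmentProfile]) -> pd.DataFrame:
    """Tidy long-format table: subject_id, hemisphere, parameter, segment, median, n_voxels."""
    records = []
    for p in sorted(profiles, key=lambda p: (p.subject_id, p.hemisphere, p.parameter)):
        for k in range(p.n_segments):
            records.append(
                {
                    "subject_id": p.subject_id,
                    "hemisphere": p.hemisphere,
                    "parameter": p.parameter,
                    "segment": k + 1,
                    "median": p.values[k],
                    "n_voxels": int(p.n_voxels[k]),
                }
            )
    return pd.DataFrame(records)
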