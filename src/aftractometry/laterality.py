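"""Hemispheric laterality index from thresholded fMRI activation maps.

LI = (Left - Right) / (Left + Right) over the counts of suprathreshold
voxels inside homologous left/right ROIs: +1 is fully left-lateralized
(typical language dominance), -1 fully right.  Homology is supplied as
explicit paired masks so any atlas parcellation works.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import ScalarVolume

logger = logging.getLogger(__name__)

__all__ = [
    "threshold_zmap",
    "count_in_roi",
    "laterality_index",
    "LateralityResult",
    "compute_laterality",
]


def threshold_zmap(zmap: ScalarVolume, z_thresh: float = 3.1, strict: bool = True) -> ScalarVolume:
    """Binary activation volume at the Z threshold (strict '>' by default)."""
    z = np.asarray(zmap.data, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("Z-map contains non-finite values")
    active = z > z_thresh if strict else z >= z_thresh
    return ScalarVolume(active.astype(np.uint8), zmap.affine)


def count_in_roi(activation: ScalarVolume, roi_mask: ScalarVolume) -> int:
    """Number of activated voxels inside the ROI."""
    if not activation.same_grid(roi_mask):
        raise ValueError("activation and ROI mask are not on the same grid")
    return int(np.sum(activation.data.astype(bool) & roi_mask.data.astype(bool)))


def laterality_index(n_left: int, n_right: int) -> float:
    """(L - R)/(L + R); NaN with a warning when no voxel is active on either side."""
    if n_left < 0 or n_right < 0:
        raise ValueError(f"voxel counts must be non-negative, got ({n_left}, {n_right})")
    total = n_left + n_right
    if total == 0:
        logger.warning("no suprathreshold voxels on either side; LI undefined")
        return float("nan")
    return (n_left - n_right) / total


@dataclass
class LateralityResult:
    lobe: str
    n_left: int
    n_right: int
    li: float


def compute_laterality(
    zmap: ScalarVolume,
    roi_pairs: dict[str, tuple[ScalarVolume, ScalarVolume]],
    z_thresh: float = 3.1,
    strict: bool = True,
) -> pd.DataFrame:
    """LI per lobe from a Z-map and {lobe: (left mask, right mask)} pairs."""
    activation = threshold_zmap(zmap, z_thresh, strict)
    rows = []
    for lobe in sorted(roi_pairs):
        left, right = roi_pairs[lobe]
        nl = count_in_roi(activation, left)
        nr = count_in_roi(activation, right)
        rows.append(
            LateralityResult(lobe=lobe, n_left=nl, n_right=nr, li=laterality_index(nl, nr))
        )
    return pd.DataFrame([r.__dict__ for r in rows])
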