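"""Healthy-control normative ranges and abnormal-segment classification.

The normative model is fitted per DTI parameter and hemisphere from a
(subjects x segments) matrix of healthy-control segment medians:

1. de-median: within each segment the across-subject median m_k is
   subtracted, pooling all segments of the parameter onto one
   distribution of deviations;
2. outlier trimming: pooled deviations farther than ``factor`` (default
   3) times the mean absolute deviation about the median are dropped —
   the mean absolute deviation is used literally, not the conventional
   median-based MAD (a flag switches);
3. the 2.5th–97.5th percentile band is estimated parametrically from the
   trimmed standard deviation: halfwidth h = 1.959964 sigma, giving the
   per-segment normative interval [m_k - h, m_k + h].

Patient segment medians strictly below the interval are "low", strictly
above "high"; boundary values are normal.  No outlier trimming is ever
applied to patients — out-of-range values are exactly what the method is
meant to detect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tractometry import SegmentProfile

logger = logging.getLogger(__name__)

__all__ = [
    "demedian",
    "remove_outliers",
    "NormativeRangeModel",
    "NormativeRangeResults",
    "classify_segments",
    "summarize_subject",
    "SubjectMetrics",
    "GAUSSIAN_975_QUANTILE",
]

GAUSSIAN_975_QUANTILE = 1.959964

#: direction in which each DTI parameter becomes abnormal with injury
ABNORMAL_DIRECTION = {"FA": "low", "AD": "low", "MD": "high", "RD": "high"}


def demedian(hc_matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Subtract the per-segment across-subject median from each entry.

    Returns ``(deviations, segment_medians)``.  Requires at least 2
    finite values per segment; a segment missing in more than half the
    controls is refused since its median would be unreliable.
    """
    mat = hc_matrix.astype(float)
    n_sub = len(mat)
    if n_sub < 2:
        raise ValueError("need at least 2 healthy controls")
    finite = mat.notna().sum(axis=0)
    bad = finite[finite < max(2, n_sub / 2)]
    if len(bad):
        raise ValueError(
            f"segments {list(bad.index)} are missing in too many controls "
            f"({n_sub} subjects)"
        )
    m_k = mat.median(axis=0, skipna=True)
    return mat - m_k, m_k


def remove_outliers(
    values: np.ndarray, factor: float = 3.0, kind: str = "mean"
) -> tuple[np.ndarray, int]:
    """Trim values beyond ``factor`` x the (mean|median) absolute deviation.

    Deviations are measured about the median of the pooled values.
    Returns ``(kept, n_removed)``.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 10:
        raise ValueError(f"need >= 10 pooled values for outlier trimming, got {v.size}")
    med = np.median(v)
    absdev = np.abs(v - med)
    if kind == "mean":
        mad = absdev.mean()
    elif kind == "median":
        mad = np.median(absdev)
    else:
        raise ValueError(f"kind must be 'mean' or 'median', got {kind}")
    if mad == 0:
        logger.warning("all pooled values identical; nothing to trim")
        return v, 0
    keep = absdev <= factor * mad
    return v[keep], int((~keep).sum())


class NormativeRangeModel:
    """Normative along-tract range for one DTI parameter and hemisphere.

    Parameters
    ----------
    hc_matrix : DataFrame
        Healthy-control segment medians, subjects in rows, segments
        1..K in columns.
    parameter : str
        DTI parameter name (FA, MD, AD, RD) — recorded and checked at
        classification time.
    hemisphere : str
        'L' or 'R'; ranges are always built separately per side.
    mad_factor : float
        Trimming threshold in units of the mean absolute deviation.
    mad_kind : {'mean', 'median'}
        Literal mean absolute deviation (default) or conventional MAD.
    coverage_z : float
        Half-width multiplier on the trimmed SD; the default 1.959964
        puts the band at the Gaussian 2.5th–97.5th percentiles.
    sd_ddof : int
        Delta degrees of freedom of the trimmed SD (default 1).
    """

    def __init__(
        self,
        hc_matrix: pd.DataFrame,
        parameter: str = "",
        hemisphere: str = "L",
        *,
        mad_factor: float = 3.0,
        mad_kind: str = "mean",
        coverage_z: float = GAUSSIAN_975_QUANTILE,
        sd_ddof: int = 1,
    ) -> None:
        self.hc_matrix = hc_matrix
        self.parameter = parameter
        self.hemisphere = hemisphere
        self.mad_factor = mad_factor
        self.mad_kind = mad_kind
        self.coverage_z = coverage_z
        self.sd_ddof = sd_ddof

    def fit(self) -> "NormativeRangeResults":
        deviations, m_k = demedian(self.hc_matrix)
        pooled = deviations.to_numpy().ravel()
        pooled = pooled[np.isfinite(pooled)]
        kept, n_removed = remove_outliers(pooled, self.mad_factor, self.mad_kind)
        if kept.size < 10:
            raise ValueError(f"only {kept.size} values kept after trimming; need >= 10")
        sigma = float(np.std(kept, ddof=self.sd_ddof))
        halfwidth = self.coverage_z * sigma
        return NormativeRangeResults(
            model=self,
            segment_medians=m_k,
            sigma=sigma,
            halfwidth=halfwidth,
            n_outliers_removed=n_removed,
            n_values_total=int(pooled.size),
        )


@dataclass
class NormativeRangeResults:
    """Fitted normative band: per-segment interval [m_k - h, m_k + h]."""

    model: NormativeRangeModel
    segment_medians: pd.Series
    sigma: float
    halfwidth: float
    n_outliers_removed: int
    n_values_total: int

    @property
    def parameter(self) -> str:
        return self.model.parameter

    @property
    def hemisphere(self) -> str:
        return self.model.hemisphere

    @property
    def n_segments(self) -> int:
        return len(self.segment_medians)

    def intervals(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "median": self.segment_medians,
                "lo": self.segment_medians - self.halfwidth,
                "hi": self.segment_medians + self.halfwidth,
            }
        )

    def classify(self, values: np.ndarray) -> np.ndarray:
        """Per-segment flags: 'low' | 'high' | 'normal' | 'missing'.

        Strictly below the 2.5th-percentile edge is low, strictly above
        the 97.5th is high; values exactly on an edge are normal.
        """
        v = np.asarray(values, dtype=float)
        if v.shape != (self.n_segments,):
            raise ValueError(
                f"expected {self.n_segments} segment values, got shape {v.shape}"
            )
        lo = self.segment_medians.to_numpy() - self.halfwidth
        hi = self.segment_medians.to_numpy() + self.halfwidth
        flags = np.where(v < lo, "low", np.where(v > hi, "high", "normal"))
        flags = np.where(np.isfinite(v), flags, "missing")
        return flags

    def coverage(self, matrix: pd.DataFrame) -> float:
        """Fraction of finite segment values inside their own interval."""
        v = matrix.to_numpy(dtype=float)
        lo = self.segment_medians.to_numpy() - self.halfwidth
        hi = self.segment_medians.to_numpy() + self.halfwidth
        finite = np.isfinite(v)
        inside = (v >= lo) & (v <= hi) & finite
        return float(inside.sum() / finite.sum())

    def to_frame(self) -> pd.DataFrame:
        df = self.intervals().reset_index().rename(columns={"index": "segment"})
        df.insert(0, "parameter", self.parameter)
        df.insert(1, "hemisphere", self.hemisphere)
        df["sigma"] = self.sigma
        df["n_outliers"] = self.n_outliers_removed
        return df

    def summary(self) -> str:
        lines = [
            f"Normative range — {self.parameter or '?'} ({self.hemisphere} hemisphere)",
            "=" * 48,
            f"segments (K):        {self.n_segments}",
            f"pooled HC values:    {self.n_values_total}",
            f"outliers removed:    {self.n_outliers_removed} "
            f"({self.n_outliers_removed / self.n_values_total:.1%}, "
            f"{self.model.mad_factor:g} x {self.model.mad_kind} abs. deviation)",
            f"trimmed SD:          {self.sigma:.5f}",
            f"band halfwidth:      {self.halfwidth:.5f} "
            f"(+/- {self.model.coverage_z:g} SD, 2.5th–97.5th pct)",
            "",
            self.intervals().round(5).to_string(),
        ]
        return "\n".join(lines)


def classify_segments(
    profile: SegmentProfile, results: NormativeRangeResults
) -> np.ndarray:
    """Classify a patient profile against a fitted normative range.

    The profile must match the model's parameter, hemisphere and K.
    """
    if results.parameter and profile.parameter and results.parameter != profile.parameter:
        raise ValueError(
            f"parameter mismatch: profile {profile.parameter} vs model {results.parameter}"
        )
    if results.hemisphere and profile.hemisphere and results.hemisphere != profile.hemisphere:
        raise ValueError(
            f"hemisphere mismatch: profile {profile.hemisphere} vs model {results.hemisphere}"
        )
    return results.classify(profile.values)


@dataclass
class SubjectMetrics:
    """Per-subject summary: abnormal-segment counts and across-segment medians.

    The directional counts follow the injury signature — decreased
    FA/AD, increased MD/RD; the two-sided sets keep every out-of-band
    segment regardless of direction.
    """

    subject_id: str
    group: str
    abnormal_count: dict[str, int] = field(default_factory=dict)
    abnormal_two_sided: dict[str, frozenset[int]] = field(default_factory=dict)
    median_across_segments: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"subject_id": self.subject_id, "group": self.group}
        for p, c in sorted(self.abnormal_count.items()):
            word = "decreased" if ABNORMAL_DIRECTION.get(p) == "low" else "increased"
            row[f"{p} # {word} segments"] = c
        for p, m in sorted(self.median_across_segments.items()):
            row[f"Median {p}"] = m
        return row


def summarize_subject(
    subject_id: str,
    group: str,
    flags_by_parameter: dict[str, np.ndarray],
    profiles_by_parameter: dict[str, SegmentProfile],
) -> SubjectMetrics:
    """Abnormal-segment counts (directional + two-sided) and profile medians."""
    metrics = SubjectMetrics(subject_id=subject_id, group=group)
    for p, flags in flags_by_parameter.items():
        direction = ABNORMAL_DIRECTION.get(p)
        if direction is None:
            raise ValueError(f"unknown DTI parameter {p!r}")
        flags = np.asarray(flags)
        metrics.abnormal_count[p] = int((flags == direction).sum())
        metrics.abnormal_two_sided[p] = frozenset(
            int(k + 1) for k in np.flatnonzero((flags == "low") | (flags == "high"))
        )
    for p, prof in profiles_by_parameter.items():
        metrics.median_across_segments[p] = prof.median_across_segments()
    return metrics
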