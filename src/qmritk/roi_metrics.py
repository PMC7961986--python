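"""ROI-level histogram statistics of parametric maps and group summaries.

Statistics are computed from raw voxel values, never from binned
histograms. Kurtosis uses the non-excess moment-ratio convention
(normal -> 3); SD uses the n-1 denominator; skewness and kurtosis use
population central moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VoxelSample",
    "HistogramStats",
    "histogram_stats",
    "relative_group_difference",
    "cohort_summary",
    "fd_bin_edges",
]


@dataclass(frozen=True)
class VoxelSample:
    """Finite per-voxel metric values within one ROI."""

    values: np.ndarray
    metric: str = ""
    subject_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError("empty voxel sample")
        if not np.all(np.isfinite(v)):
            raise ValueError("voxel sample contains non-finite values")
        object.__setattr__(self, "values", v)


@dataclass
class HistogramStats:
    n: int
    mean: float
    sd: float
    skewness: float  # NaN when sd == 0
    kurtosis: float  # non-excess; NaN when sd == 0


def histogram_stats(sample: VoxelSample) -> HistogramStats:
    """Mean, SD (n-1), skewness m3/m2^1.5 and kurtosis m4/m2^2 of an ROI sample."""
    v = sample.values
    n = v.size
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if n > 1 else np.nan
    d = v - mean
    m2 = float(np.mean(d ** 2))
    if m2 == 0 or n == 1:
        return HistogramStats(n, mean, 0.0 if n > 1 else np.nan, np.nan, np.nan)
    z = d / np.sqrt(m2)  # standardize before higher powers (underflow-safe)
    return HistogramStats(n, mean, sd, float(np.mean(z ** 3)),
                          float(np.mean(z ** 4)))


def relative_group_difference(mean_with: float, mean_without: float) -> int:
    """Percent difference of group means relative to the with-event group.

    ``100 * |mean_without - mean_with| / mean_with``, rounded to the
    nearest integer percent.
    """
    if mean_with == 0:
        raise ValueError("reference (with-event) mean must be nonzero")
    return int(round(100.0 * abs(mean_without - mean_with) / abs(mean_with)))


def cohort_summary(samples, groups) -> pd.DataFrame:
    """Per-group mean and SD of subject-level ROI means, per metric.

    Parameters
    ----------
    samples : iterable of VoxelSample
    groups : mapping of subject_id -> group label

    Returns a tidy frame indexed by (metric, group) with columns
    n_subjects, mean, sd.
    """
    rows = []
    for s in samples:
        if s.subject_id not in groups:
            raise ValueError(f"unknown group label for subject {s.subject_id!r}")
        rows.append({"subject_id": s.subject_id, "metric": s.metric,
                     "group": groups[s.subject_id],
                     "subject_mean": float(np.mean(s.values))})
    df = pd.DataFrame(rows)
    out = (df.groupby(["metric", "group"])["subject_mean"]
             .agg(n_subjects="size", mean="mean", sd=lambda x: x.std(ddof=1))
             .reset_index())
    out["sd"] = out["sd"].fillna(0.0)
    return out


def fd_bin_edges(values: np.ndarray) -> np.ndarray:
    """Freedman-Diaconis histogram bin edges (plotting only)."""
    return np.histogram_bin_edges(np.asarray(values, dtype=float), bins="fd")
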