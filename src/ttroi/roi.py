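"""Temporal aggregation of cancer tags into regions of interest (ROIs).

A frame-wise detector tags individual frames, so a single lesion viewed for a
minute produces thousands of scattered cancer tags.  The video-level decision
statistic aggregates them with a gap rule: an ROI starts at any cancer tag and
ends when no new cancer tag appears within ``gap_s`` seconds (3 s by default).
The total time of the regions of interest (TTROI) — the summed ROI durations —
is the per-video statistic thresholded downstream.

Conventions (configurable where noted):

* the gap comparison is closed: tags exactly ``gap_s`` apart join one ROI;
* an ROI's end is the timestamp of its last cancer tag (``roi_end="last_tag"``);
  the alternative ``"last_tag_plus_gap"`` extends each ROI by the gap, clipped
  to the video duration;
* a single isolated tag forms a zero-duration ROI, so "has an ROI" is
  equivalent to "has at least one cancer tag";
* timestamps are used as-is, never snapped to a frame grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .streams import FrameSeries

__all__ = ["ROI", "VideoSummary", "extract_rois", "summarize_video",
           "summarize_cohort", "ROIExtractor"]

ROI_END_CONVENTIONS = ("last_tag", "last_tag_plus_gap")


@dataclass(frozen=True)
class ROI:
    """A maximal run of cancer tags with inter-tag gaps ≤ the gap rule."""

    start_s: float
    end_s: float
    n_tags: int

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValueError("ROI ends before it starts")
        if self.n_tags < 1:
            raise ValueError("ROI must contain at least one tag")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class VideoSummary:
    """Per-video ROI summary: the ROIs, their total time, and whether any
    cancer tag occurred at all (the "no ROI" indicator is ``not has_roi``)."""

    video_id: str
    rois: tuple[ROI, ...]
    ttroi_s: float
    has_roi: bool
    duration_s: float

    @property
    def n_rois(self) -> int:
        return len(self.rois)


def extract_rois(
    series: FrameSeries, gap_s: float = 3.0, roi_end: str = "last_tag"
) -> list[ROI]:
    """Merge the series' cancer tags into time-ordered, disjoint ROIs.

    Cancer-tagged timestamps (duplicates collapsed) are partitioned into
    maximal runs in which consecutive tags are at most ``gap_s`` apart; each
    run becomes one ROI.  A series with no cancer tag yields an empty list.
    An empty series is an error.
    """
    if gap_s <= 0:
        raise ValueError("gap_s must be positive")
    if roi_end not in ROI_END_CONVENTIONS:
        raise ValueError(f"roi_end must be one of {ROI_END_CONVENTIONS}")
    if len(series) == 0:
        raise ValueError("empty series")
    ct = series.cancer_times()
    if ct.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(ct) > gap_s)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [ct.size - 1]))
    rois = []
    for i0, i1 in zip(starts, ends):
        end = float(ct[i1])
        if roi_end == "last_tag_plus_gap":
            end = min(end + gap_s, series.duration_s)
        rois.append(ROI(float(ct[i0]), end, int(i1 - i0 + 1)))
    return rois


def summarize_video(
    series: FrameSeries, gap_s: float = 3.0, roi_end: str = "last_tag"
) -> VideoSummary:
    """ROI extraction plus the TTROI statistic for one video."""
    rois = extract_rois(series, gap_s=gap_s, roi_end=roi_end)
    ttroi = float(sum(r.duration_s for r in rois))
    return VideoSummary(
        video_id=series.video_id,
        rois=tuple(rois),
        ttroi_s=ttroi,
        has_roi=bool(rois),
        duration_s=series.duration_s,
    )


def summarize_cohort(
    series_iter: Iterable[FrameSeries], gap_s: float = 3.0, roi_end: str = "last_tag"
) -> pd.DataFrame:
    """Per-video summary table: video_id, n_rois, ttroi_s, has_roi, duration_s."""
    rows = []
    for series in series_iter:
        s = summarize_video(series, gap_s=gap_s, roi_end=roi_end)
        rows.append((s.video_id, s.n_rois, s.ttroi_s, s.has_roi, s.duration_s))
    return pd.DataFrame(
        rows, columns=["video_id", "n_rois", "ttroi_s", "has_roi", "duration_s"]
    )


class ROIExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer from frame streams to per-video ROI summaries.

    ``transform`` maps an iterable of :class:`FrameSeries` to the summary
    DataFrame of :func:`summarize_cohort`.  Exposed as an estimator so the
    stream→TTROI→classification pipeline composes with scikit-learn tooling.

    Parameters
    ----------
    gap_s : float, default 3.0
        Maximum silence between consecutive cancer tags inside one ROI.
    roi_end : {"last_tag", "last_tag_plus_gap"}, default "last_tag"
        ROI end-time convention.
    """

    def __init__(self, gap_s: float = 3.0, roi_end: str = "last_tag"):
        self.gap_s = gap_s
        self.roi_end = roi_end

    def fit(self, X: Sequence[FrameSeries] | None = None, y=None) -> "ROIExtractor":
        if self.gap_s <= 0:
            raise ValueError("gap_s must be positive")
        if self.roi_end not in ROI_END_CONVENTIONS:
            raise ValueError(f"roi_end must be one of {ROI_END_CONVENTIONS}")
        self.n_features_in_ = 1
        return self

    def transform(self, X: Iterable[FrameSeries]) -> pd.DataFrame:
        return summarize_cohort(X, gap_s=self.gap_s, roi_end=self.roi_end)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = False
        tags.no_validation = True
        return tags
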