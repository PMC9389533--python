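"""Per-frame detection streams and per-video metadata.

A frame-wise lesion detector running over a magnifying-endoscopy video emits,
for every frame, one of four tags: ``cancer`` (early-gastric-cancer features),
``benign`` (a benign lesion that must be distinguished from cancer),
``background`` (unremarkable mucosa) and ``none`` (no rectangle drawn at all —
distinct from an explicit background call).  This module defines the in-memory
containers for such streams, their JSONL and CSV dialects, and the per-video
ground-truth metadata keyed to the revised Vienna classification (C1–C5, with
C4/C5 defining cancer).

Streams are stored columnwise (numpy arrays) so that downstream interval
merging stays vectorised; :class:`FrameRecord` is the record-level view used
for I/O and validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LABELS",
    "PATHOLOGIES",
    "CANCER_PATHOLOGIES",
    "VIENNA_CATEGORIES",
    "FrameRecord",
    "FrameSeries",
    "VideoMeta",
    "map_vienna_to_truth",
    "collapse_frame",
    "collapse_series",
    "read_detection_stream",
    "write_detection_stream",
    "read_metadata",
    "write_metadata",
]

#: Closed label vocabulary, in priority order (highest first).
LABELS = ("cancer", "benign", "background", "none")
LABEL_CODES = {lab: i for i, lab in enumerate(LABELS)}
CANCER, BENIGN, BACKGROUND, NONE = range(4)

PATHOLOGIES = (
    "inflammation",
    "atrophy",
    "IM",
    "atrophy_IM",
    "LGIN",
    "EGC_poor_diff",
    "EGC_diff",
)
CANCER_PATHOLOGIES = frozenset({"EGC_poor_diff", "EGC_diff"})
VIENNA_CATEGORIES = ("C1", "C2", "C3", "C4", "C5")

_CSV_COLUMNS = ["video_id", "t", "label", "confidence", "x", "y", "w", "h"]
_META_COLUMNS = [
    "video_id",
    "pathology",
    "vienna",
    "truth",
    "severity",
    "range",
    "location",
    "sex",
]


def map_vienna_to_truth(category: str) -> str:
    """Binary gold standard from the revised Vienna category.

    C4 (mucosal high-grade neoplasia) and C5 (submucosal invasion) are
    ``cancer``; C1 (negative), C2 (indefinite) and C3 (low-grade
    intraepithelial neoplasia) are ``non_cancer``.
    """
    if category not in VIENNA_CATEGORIES:
        raise ValueError(f"unknown Vienna category: {category!r}")
    return "cancer" if category in ("C4", "C5") else "non_cancer"


def collapse_frame(labels: Iterable[str]) -> str:
    """Collapse co-timed record labels to one frame label.

    An object detector may emit several rectangles for the same frame; the
    frame diagnosis is the highest-priority label present, with priority
    cancer > benign > background > none.
    """
    codes = []
    for lab in labels:
        if lab not in LABEL_CODES:
            raise ValueError(f"unknown label: {lab!r}")
        codes.append(LABEL_CODES[lab])
    if not codes:
        raise ValueError("no records to collapse")
    return LABELS[min(codes)]


def _validate_box(box: Sequence[float], where: str = "") -> tuple[float, ...]:
    box = tuple(float(v) for v in box)
    if len(box) != 4:
        raise ValueError(f"box must have 4 entries{where}")
    x, y, w, h = box
    eps = 1e-9
    ok = (
        -eps <= x <= 1 + eps
        and -eps <= y <= 1 + eps
        and eps < w <= 1 + eps
        and eps < h <= 1 + eps
        and x + w <= 1 + eps
        and y + h <= 1 + eps
    )
    if not ok:
        raise ValueError(f"box out of the unit square{where}: {box}")
    return box


@dataclass(frozen=True)
class FrameRecord:
    """One detector emission: a timestamped label, optionally with a
    confidence and a normalized bounding box (x, y, w, h)."""

    video_id: str
    t: float
    label: str
    confidence: float | None = None
    box: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"negative timestamp: {self.t}")
        if self.label not in LABEL_CODES:
            raise ValueError(f"unknown label: {self.label!r}")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence outside [0, 1]: {self.confidence}")
        if self.box is not None:
            object.__setattr__(self, "box", _validate_box(self.box))


class FrameSeries:
    """Detector output for one video, stored columnwise.

    Parameters
    ----------
    video_id : str
    t : array-like of float
        Seconds from video start; sorted non-decreasing (unsorted input is
        sorted with a warning).  Duplicate timestamps are legal — a detector
        can emit several boxes per frame — and are collapsed by label
        priority before ROI extraction.
    labels : array-like of str or int codes
        Frame tags from the closed vocabulary.
    duration_s : float, optional
        Video length; defaults to the last timestamp.
    fps : float
        Nominal frame rate (default 30).
    confidence : array-like of float, optional
        Per-record confidence, NaN where absent.
    boxes : array-like of shape (n, 4), optional
        Normalized boxes, NaN rows where absent.
    """

    def __init__(
        self,
        video_id: str,
        t,
        labels,
        duration_s: float | None = None,
        fps: float = 30.0,
        confidence=None,
        boxes=None,
    ) -> None:
        t = np.asarray(t, dtype=float)
        codes = self._encode(labels, t.size)
        confidence = (
            np.full(t.size, np.nan) if confidence is None else np.asarray(confidence, float)
        )
        boxes = (
            np.full((t.size, 4), np.nan) if boxes is None else np.asarray(boxes, float)
        )
        if not (t.size == codes.size == confidence.size == boxes.shape[0]):
            raise ValueError("column lengths differ")
        if t.size and np.any(np.diff(t) < 0):
            warnings.warn(
                f"records for {video_id!r} not sorted by t; sorting", stacklevel=2
            )
            order = np.argsort(t, kind="stable")
            t, codes = t[order], codes[order]
            confidence, boxes = confidence[order], boxes[order]
        if t.size and t[0] < 0:
            raise ValueError("negative timestamps")
        if duration_s is None:
            duration_s = float(t[-1]) if t.size else 0.0
        if t.size and t[-1] > duration_s + 1e-9:
            raise ValueError(
                f"timestamps exceed duration ({t[-1]:.3f} > {duration_s:.3f})"
            )
        if fps <= 0:
            raise ValueError("fps must be positive")
        finite_conf = confidence[np.isfinite(confidence)]
        if finite_conf.size and (finite_conf.min() < 0 or finite_conf.max() > 1):
            raise ValueError("confidence outside [0, 1]")
        for i in np.flatnonzero(np.isfinite(boxes).any(axis=1)):
            _validate_box(boxes[i], where=f" (record {i})")
        self.video_id = str(video_id)
        self.t = t
        self.label_codes = codes
        self.duration_s = float(duration_s)
        self.fps = float(fps)
        self.confidence = confidence
        self.boxes = boxes

    @staticmethod
    def _encode(labels, n: int) -> np.ndarray:
        arr = np.asarray(labels)
        if arr.dtype.kind in "iu":
            codes = arr.astype(np.int8)
            if codes.size and (codes.min() < 0 or codes.max() >= len(LABELS)):
                raise ValueError("label code out of range")
            return codes
        codes = np.empty(arr.size, dtype=np.int8)
        for i, lab in enumerate(arr.ravel()):
            try:
                codes[i] = LABEL_CODES[lab]
            except KeyError:
                raise ValueError(f"unknown label: {lab!r}") from None
        return codes

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return self.t.size

    def __repr__(self) -> str:
        return (
            f"FrameSeries({self.video_id!r}, n={len(self)}, "
            f"duration={self.duration_s:.1f}s, fps={self.fps:g})"
        )

    @property
    def labels(self) -> np.ndarray:
        """Frame tags as strings."""
        return np.asarray(LABELS, dtype=object)[self.label_codes]

    def records(self) -> Iterator[FrameRecord]:
        for i in range(len(self)):
            conf = self.confidence[i]
            box = self.boxes[i]
            yield FrameRecord(
                self.video_id,
                float(self.t[i]),
                LABELS[self.label_codes[i]],
                confidence=None if np.isnan(conf) else float(conf),
                box=None if np.isnan(box).any() else tuple(float(v) for v in box),
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[FrameRecord],
        duration_s: float | None = None,
        fps: float = 30.0,
    ) -> "FrameSeries":
        records = list(records)
        if not records:
            raise ValueError("empty stream")
        vids = {r.video_id for r in records}
        if len(vids) > 1:
            raise ValueError(f"records span several videos: {sorted(vids)}")
        t = [r.t for r in records]
        labels = [r.label for r in records]
        conf = [np.nan if r.confidence is None else r.confidence for r in records]
        boxes = [(np.nan,) * 4 if r.box is None else r.box for r in records]
        return cls(
            records[0].video_id, t, labels, duration_s=duration_s, fps=fps,
            confidence=conf, boxes=np.asarray(boxes, float),
        )

    def equals(self, other: "FrameSeries", rtol: float = 1e-6) -> bool:
        """Equality up to float formatting (≥6 significant digits)."""
        if self.video_id != other.video_id or len(self) != len(other):
            return False
        if not np.array_equal(self.label_codes, other.label_codes):
            return False
        close = lambda a, b: np.allclose(a, b, rtol=rtol, atol=1e-12, equal_nan=True)
        return (
            close(self.t, other.t)
            and close(self.confidence, other.confidence)
            and close(self.boxes, other.boxes)
            and np.isclose(self.duration_s, other.duration_s, rtol=rtol)
        )

    def cancer_times(self) -> np.ndarray:
        """Unique timestamps carrying a cancer tag (duplicates collapsed)."""
        return np.unique(self.t[self.label_codes == CANCER])


def collapse_series(series: FrameSeries) -> FrameSeries:
    """One record per distinct timestamp, labels collapsed by priority."""
    t_unique, inverse = np.unique(series.t, return_inverse=True)
    codes = np.full(t_unique.size, NONE, dtype=np.int8)
    np.minimum.at(codes, inverse, series.label_codes)
    return FrameSeries(
        series.video_id, t_unique, codes,
        duration_s=series.duration_s, fps=series.fps,
    )


@dataclass(frozen=True)
class VideoMeta:
    """Ground truth for one video.

    ``truth`` must agree with the Vienna category (C4/C5 → cancer), and the
    EGC pathology subtypes are exactly the cancer videos.  ``severity``,
    ``range``, ``location`` and ``sex`` are the univariate-analysis covariates
    and may be absent.
    """

    video_id: str
    pathology: str
    vienna: str
    truth: str | None = None
    severity: str | None = None
    range: str | None = None
    location: str | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.pathology not in PATHOLOGIES:
            raise ValueError(f"unknown pathology: {self.pathology!r}")
        derived = map_vienna_to_truth(self.vienna)
        if self.truth is None:
            object.__setattr__(self, "truth", derived)
        elif self.truth != derived:
            raise ValueError(
                f"truth {self.truth!r} inconsistent with Vienna {self.vienna}"
            )
        is_egc = self.pathology in CANCER_PATHOLOGIES
        if is_egc != (self.truth == "cancer"):
            raise ValueError(
                f"pathology {self.pathology!r} inconsistent with truth {self.truth!r}"
            )
        for attr, allowed in (
            ("severity", ("mild", "moderate_severe")),
            ("range", ("local", "diffuse")),
            ("location", ("upper", "lower")),
            ("sex", ("male", "female")),
        ):
            val = getattr(self, attr)
            if val is not None and val not in allowed:
                raise ValueError(f"{attr} must be one of {allowed}, got {val!r}")


# -- stream I/O -------------------------------------------------------------


def _infer_dialect(path: Path) -> str:
    if path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    if path.suffix.lower() in (".csv", ".tsv"):
        return "csv"
    raise ValueError(f"cannot infer dialect from {path.name!r}; pass dialect=")


def read_detection_stream(
    path, dialect: str | None = None, fps: float = 30.0,
    duration_s: float | None = None,
) -> FrameSeries:
    """Read one video's detection stream from JSONL or CSV.

    JSONL carries one object per line with keys ``video_id``, ``t``,
    ``label`` and optional ``confidence`` and ``box`` (length-4 array); the
    CSV dialect has header ``video_id,t,label,confidence,x,y,w,h`` with empty
    cells for absent optionals.  Unknown labels and missing required fields
    are parse errors naming the offending line.
    """
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "jsonl":
        records = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path.name}, line {lineno}: bad JSON ({exc})")
                for key in ("video_id", "t", "label"):
                    if key not in obj:
                        raise ValueError(
                            f"{path.name}, line {lineno}: missing field {key!r}"
                        )
                try:
                    records.append(
                        FrameRecord(
                            str(obj["video_id"]), float(obj["t"]), obj["label"],
                            confidence=obj.get("confidence"),
                            box=tuple(obj["box"]) if obj.get("box") is not None else None,
                        )
                    )
                except ValueError as exc:
                    raise ValueError(f"{path.name}, line {lineno}: {exc}") from None
    elif dialect == "csv":
        frame = pd.read_csv(path)
        if frame.empty:
            raise ValueError("empty stream")
        missing = {"video_id", "t", "label"} - set(frame.columns)
        if missing:
            raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
        records = []
        for idx, row in frame.iterrows():
            lineno = idx + 2  # header is line 1
            if pd.isna(row["video_id"]) or pd.isna(row["t"]) or pd.isna(row["label"]):
                raise ValueError(f"{path.name}, line {lineno}: missing required field")
            box = None
            vals = [row.get(k, np.nan) for k in ("x", "y", "w", "h")]
            if not any(pd.isna(v) for v in vals):
                box = tuple(float(v) for v in vals)
            conf = row.get("confidence", np.nan)
            try:
                records.append(
                    FrameRecord(
                        str(row["video_id"]), float(row["t"]), str(row["label"]),
                        confidence=None if pd.isna(conf) else float(conf),
                        box=box,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path.name}, line {lineno}: {exc}") from None
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    if not records:
        raise ValueError("empty stream")
    return FrameSeries.from_records(records, duration_s=duration_s, fps=fps)


def write_detection_stream(series: FrameSeries, path, dialect: str | None = None) -> None:
    """Write a stream so that reading it back reproduces the series (round
    trip exact for JSONL, ≥6 significant digits for CSV)."""
    if len(series) == 0:
        raise ValueError("refusing to write an empty stream")
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in series.records():
                obj: dict = {"video_id": rec.video_id, "t": rec.t, "label": rec.label}
                if rec.confidence is not None:
                    obj["confidence"] = rec.confidence
                if rec.box is not None:
                    obj["box"] = list(rec.box)
                fh.write(json.dumps(obj) + "\n")
    elif dialect == "csv":
        rows = []
        for rec in series.records():
            box = rec.box or (np.nan,) * 4
            rows.append(
                (rec.video_id, rec.t, rec.label,
                 np.nan if rec.confidence is None else rec.confidence, *box)
            )
        frame = pd.DataFrame(rows, columns=_CSV_COLUMNS)
        frame.to_csv(path, index=False, float_format="%.9g")
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


# -- metadata I/O -----------------------------------------------------------


def read_metadata(path) -> list[VideoMeta]:
    """Read the per-video metadata CSV; ``truth`` is derived from the Vienna
    category when the column is absent or empty."""
    frame = pd.read_csv(path)
    missing = {"video_id", "pathology", "vienna"} - set(frame.columns)
    if missing:
        raise ValueError(f"metadata missing columns {sorted(missing)}")
    metas = []
    for _, row in frame.iterrows():
        get = lambda key: (
            None if key not in frame.columns or pd.isna(row[key]) else str(row[key])
        )
        metas.append(
            VideoMeta(
                str(row["video_id"]), str(row["pathology"]), str(row["vienna"]),
                truth=get("truth"), severity=get("severity"), range=get("range"),
                location=get("location"), sex=get("sex"),
            )
        )
    return metas


def write_metadata(metas: Sequence[VideoMeta], path) -> None:
    frame = pd.DataFrame(
        [[getattr(m, c) for c in _META_COLUMNS] for m in metas],
        columns=_META_COLUMNS,
    )
    frame.to_csv(path, index=False)
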