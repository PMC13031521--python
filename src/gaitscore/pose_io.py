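"""Reading, validating and preprocessing 2D pose-estimator output.

The on-disk dialect is the AlphaPose result format: a JSON array of records,
one per detected person per frame, each carrying an image identifier, a flat
list of 51 floats (17 keypoints x (x, y, confidence) in COCO order), a
detection score and a person index.  A video's walk becomes a
:class:`PoseSequence`: one retained person, frames ordered by index, plus the
clinical metadata (subject, visit, SARA gait grade, demographics) needed by
the downstream modeling.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import (
    DegenerateChannelError,
    EmptyInputError,
    FormatError,
    InvalidArgumentError,
    ParseError,
)
from .skeleton import COCO_KEYPOINTS, KEYPOINT_INDEX, N_KEYPOINTS

logger = logging.getLogger(__name__)

GRADES: tuple[str, ...] = ("HC", "0", "1", "2", "3", "4")


class Keypoint(NamedTuple):
    """One body landmark in one frame (image pixels, confidence in [0, 1])."""

    x: float
    y: float
    confidence: float


@dataclass(frozen=True)
class KeypointFrame:
    """All 17 COCO keypoints of one person in one video frame."""

    frame_index: int
    person_id: int
    score: float
    keypoints: tuple[Keypoint, ...]

    def __post_init__(self) -> None:
        if len(self.keypoints) != N_KEYPOINTS:
            raise FormatError(
                f"frame {self.frame_index}: expected {N_KEYPOINTS} keypoints, "
                f"got {len(self.keypoints)}"
            )


@dataclass
class QualityReport:
    """Per-sequence preprocessing log: which gaps exceeded ``max_gap``."""

    long_gaps: list[tuple[str, int, int]] = field(default_factory=list)
    n_interpolated: int = 0

    @property
    def flagged(self) -> bool:
        return bool(self.long_gaps)


@dataclass
class PoseSequence:
    """An ordered single-person keypoint sequence with clinical metadata.

    Parameters
    ----------
    keypoints : ndarray of shape (n_frames, 17, 3)
        Per frame and COCO keypoint: x [px], y [px], confidence in [0, 1].
    frame_indices : ndarray of shape (n_frames,)
        Strictly increasing source frame indices (gaps allowed for dropped
        frames); the time axis is ``frame_index / fps``.
    """

    keypoints: np.ndarray
    frame_indices: np.ndarray
    fps: float
    scores: np.ndarray | None = None
    person_id: int = 0
    subject_id: str = ""
    visit_id: str = ""
    visit_day: float = 0.0
    label: str | None = None
    age: float | None = None
    sex: str | None = None
    quality: QualityReport = field(default_factory=QualityReport)

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if self.keypoints.ndim != 3 or self.keypoints.shape[1:] != (N_KEYPOINTS, 3):
            raise FormatError(
                f"keypoints must have shape (n, {N_KEYPOINTS}, 3); "
                f"got {self.keypoints.shape}"
            )
        if len(self.keypoints) < 2:
            raise FormatError("a pose sequence needs at least 2 frames")
        if len(self.frame_indices) != len(self.keypoints):
            raise FormatError("frame_indices and keypoints length mismatch")
        if np.any(np.diff(self.frame_indices) <= 0):
            raise FormatError("frame indices must be strictly increasing")
        if not np.all(np.isfinite(self.keypoints[:, :, :2])):
            raise FormatError("keypoint coordinates must be finite")
        conf = self.keypoints[:, :, 2]
        if np.any(conf < 0) or np.any(conf > 1):
            raise FormatError("keypoint confidences must lie in [0, 1]")
        if self.label is not None and self.label not in GRADES:
            raise InvalidArgumentError(
                f"unknown grade label {self.label!r}; expected one of {GRADES}"
            )
        if self.scores is None:
            self.scores = np.ones(len(self.keypoints))
        else:
            self.scores = np.asarray(self.scores, dtype=float)

    def __len__(self) -> int:
        return len(self.keypoints)

    @property
    def n_frames(self) -> int:
        return len(self.keypoints)

    @property
    def times(self) -> np.ndarray:
        """Time stamps in seconds (frame index over fps)."""
        return self.frame_indices / self.fps

    def marker(self, name: str) -> np.ndarray:
        """(n_frames, 2) x/y track of a named COCO keypoint."""
        return self.keypoints[:, KEYPOINT_INDEX[name], :2]

    def frame(self, i: int) -> KeypointFrame:
        kps = tuple(Keypoint(*row) for row in self.keypoints[i])
        return KeypointFrame(
            frame_index=int(self.frame_indices[i]),
            person_id=self.person_id,
            score=float(self.scores[i]),
            keypoints=kps,
        )

    def is_hc(self) -> bool:
        return self.label == "HC"

    def numeric_grade(self) -> float:
        """Grade as a number; HC maps to 0 for regression-with-HC use."""
        if self.label is None:
            raise InvalidArgumentError("sequence has no grade label")
        return 0.0 if self.label == "HC" else float(self.label)


# ---------------------------------------------------------------------------
# AlphaPose JSON dialect
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"(\d+)")


def _frame_index_of(image_id: object, record_no: int) -> int:
    """Numeric part of an image identifier ('231.jpg' -> 231)."""
    if isinstance(image_id, (int, np.integer)):
        return int(image_id)
    m = _NUM_RE.search(str(image_id))
    if m is None:
        raise ParseError(
            f"record {record_no}: image_id {image_id!r} has no numeric frame part"
        )
    return int(m.group(1))


def read_alphapose_json(
    path,
    fps: float,
    metadata: dict | None = None,
    *,
    person_id: int | None = None,
) -> PoseSequence:
    """Read an AlphaPose result file into a single-person :class:`PoseSequence`.

    When multiple person indices occur, the main person is chosen by
    :func:`select_main_person`; pass ``person_id`` to override.
    ``metadata`` keys (subject_id, visit_id, visit_day, label, age, sex) are
    attached verbatim.
    """
    try:
        with open(path) as fh:
            records = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(records, list):
        raise FormatError(f"{path}: expected a JSON array of records")
    if not records:
        raise EmptyInputError(f"{path}: file contains no pose records")

    parsed = _parse_records(records)
    if person_id is None:
        person_id = select_main_person(parsed)
    track = sorted(
        (r for r in parsed if r["idx"] == person_id), key=lambda r: r["frame"]
    )
    if not track:
        raise EmptyInputError(f"{path}: no records for person {person_id}")
    # keep the best-scoring record if the estimator emitted duplicates
    by_frame: dict[int, dict] = {}
    for r in track:
        prev = by_frame.get(r["frame"])
        if prev is None or r["score"] > prev["score"]:
            by_frame[r["frame"]] = r
    frames = sorted(by_frame)
    kps = np.stack([by_frame[f]["keypoints"] for f in frames])
    scores = np.array([by_frame[f]["score"] for f in frames])
    meta = dict(metadata or {})
    return PoseSequence(
        keypoints=kps,
        frame_indices=np.array(frames),
        fps=fps,
        scores=scores,
        person_id=person_id,
        subject_id=str(meta.get("subject_id", "")),
        visit_id=str(meta.get("visit_id", "")),
        visit_day=float(meta.get("visit_day", 0.0)),
        label=meta.get("label"),
        age=meta.get("age"),
        sex=meta.get("sex"),
    )


def _parse_records(records: Sequence[dict]) -> list[dict]:
    parsed = []
    for i, rec in enumerate(records):
        if not isinstance(rec, dict) or "keypoints" not in rec:
            raise ParseError(f"record {i}: not an object with a 'keypoints' field")
        flat = rec["keypoints"]
        if len(flat) != 3 * N_KEYPOINTS:
            raise FormatError(
                f"record {i}: keypoint list has {len(flat)} values, "
                f"expected {3 * N_KEYPOINTS} (17 x/y/confidence triplets)"
            )
        kps = np.asarray(flat, dtype=float).reshape(N_KEYPOINTS, 3)
        parsed.append(
            {
                "frame": _frame_index_of(rec.get("image_id", i), i),
                "idx": int(rec.get("idx", 0)),
                "score": float(rec.get("score", 1.0)),
                "keypoints": kps,
            }
        )
    return parsed


def select_main_person(parsed: Iterable[dict]) -> int:
    """Pick the person index to retain from a multi-person file.

    The statistic is the mean over *all* frames present in the file of
    ``detection score x bounding-box area`` of that person's keypoints
    (frames where the person is absent contribute 0), so a person tracked
    throughout beats a transient detection.  Ties break to the lowest id.
    """
    parsed = list(parsed)
    if not parsed:
        raise EmptyInputError("no detections at all")
    all_frames = {r["frame"] for r in parsed}
    n = len(all_frames)
    totals: dict[int, float] = {}
    for r in parsed:
        xy = r["keypoints"][:, :2]
        area = float(np.ptp(xy[:, 0]) * np.ptp(xy[:, 1]))
        totals[r["idx"]] = totals.get(r["idx"], 0.0) + r["score"] * area
    best = max(sorted(totals), key=lambda pid: totals[pid] / n)
    return best


def write_alphapose_json(seq: PoseSequence, path) -> None:
    """Write a :class:`PoseSequence` back to the AlphaPose result dialect."""
    records = []
    for i in range(seq.n_frames):
        records.append(
            {
                "image_id": f"{int(seq.frame_indices[i])}.jpg",
                "keypoints": [round(float(v), 6) for v in seq.keypoints[i].ravel()],
                "score": round(float(seq.scores[i]), 6),
                "idx": int(seq.person_id),
            }
        )
    with open(path, "w") as fh:
        json.dump(records, fh)


REQUIRED_METADATA_COLUMNS = ("subject_id", "visit_id", "visit_day", "grade",
                             "age", "sex", "fps", "path")


def read_cohort(meta_path) -> list["PoseSequence"]:
    """Read a cohort: a metadata CSV plus the AlphaPose JSON files it lists.

    The CSV needs columns subject_id, visit_id, visit_day, grade, age, sex,
    fps, path (paths relative to the CSV's directory).
    """
    import csv as _csv
    import os as _os

    from .errors import SchemaError

    base = _os.path.dirname(_os.path.abspath(meta_path))
    sequences = []
    with open(meta_path, newline="") as fh:
        reader = _csv.DictReader(fh)
        missing = [c for c in REQUIRED_METADATA_COLUMNS
                   if c not in (reader.fieldnames or [])]
        if missing:
            raise SchemaError(f"metadata CSV missing column(s): {missing}")
        for row in reader:
            seq = read_alphapose_json(
                _os.path.join(base, row["path"]),
                fps=float(row["fps"]),
                metadata={
                    "subject_id": row["subject_id"],
                    "visit_id": row["visit_id"],
                    "visit_day": float(row["visit_day"]),
                    "label": row["grade"],
                    "age": float(row["age"]) if row["age"] else None,
                    "sex": row["sex"] or None,
                },
            )
            sequences.append(seq)
    if not sequences:
        raise EmptyInputError(f"{meta_path}: no cohort rows")
    return sequences


# ---------------------------------------------------------------------------
# Gap interpolation
# ---------------------------------------------------------------------------


def interpolate_missing(
    seq: PoseSequence,
    confidence_threshold: float = 0.3,
    max_gap: int = 5,
) -> PoseSequence:
    """Fill low-confidence keypoint observations.

    Keypoints with confidence below ``confidence_threshold`` are replaced by
    linear interpolation (in frame-index time) between the nearest flanking
    confident observations, for gaps of at most ``max_gap`` frames.  Longer
    gaps — including gaps touching the sequence edge — are filled with the
    nearest confident value and flagged in the returned sequence's
    :class:`QualityReport`.  Frames at or above the threshold are never
    modified, and the frame count is unchanged.
    """
    kps = seq.keypoints.copy()
    t = seq.frame_indices.astype(float)
    report = QualityReport()
    for k, name in enumerate(COCO_KEYPOINTS):
        conf = kps[:, k, 2]
        missing = conf < confidence_threshold
        if not missing.any():
            continue
        if missing.all():
            raise DegenerateChannelError(
                f"keypoint {name!r} is below confidence "
                f"{confidence_threshold} in every frame"
            )
        good = ~missing
        for start, stop in _runs(missing):
            gap_len = stop - start
            has_left = start > 0
            has_right = stop < len(conf)
            if gap_len <= max_gap and has_left and has_right:
                for c in (0, 1):
                    kps[start:stop, k, c] = np.interp(
                        t[start:stop], t[good], kps[good, k, c]
                    )
                report.n_interpolated += gap_len
            else:
                # nearest-value extension: each frame copies its closest
                # confident neighbour (ties resolve to the earlier frame)
                good_idx = np.flatnonzero(good)
                for j in range(start, stop):
                    nearest = good_idx[np.argmin(np.abs(t[good_idx] - t[j]))]
                    kps[j, k, :2] = kps[nearest, k, :2]
                report.long_gaps.append((name, int(start), int(stop)))
                report.n_interpolated += gap_len
                logger.warning(
                    "keypoint %s: gap of %d frames exceeds max_gap=%d; "
                    "nearest-value filled",
                    name,
                    gap_len,
                    max_gap,
                )
    out = replace(seq, keypoints=kps)
    out.quality = report
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True in a boolean mask."""
    diff = np.diff(mask.astype(int), prepend=0, append=0)
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))
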