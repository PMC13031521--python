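"""Kinematic time-series construction from pose sequences.

From each preprocessed :class:`~gaitscore.pose_io.PoseSequence` this module
builds the 16 per-frame series used throughout the analysis, grouped into
four categories:

* ``X-pos`` — 6 raw x-positions: left/right hip, wrist and ankle (pixels);
* ``Dist`` — 6 Euclidean inter-marker distances: ankle–ankle, wrist–wrist,
  hip–wrist (left, right), neck–hip (left, right) (pixels);
* ``Upper`` — 2 shoulder angles from the (wrist, shoulder, hip) triangle,
  left and right (degrees);
* ``Lower`` — 2 hip angles subtended by the two ankles, at the left and
  right hip (degrees).

COCO-17 has no neck landmark; the neck is taken as the midpoint of the two
shoulders (a standard surrogate).  Positions and distances are raw pixels —
no perspective normalization — unless ``normalize_scale`` is requested, which
divides by the per-frame trunk length (hip-centre to shoulder-centre).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateGeometryError
from .pose_io import PoseSequence

logger = logging.getLogger(__name__)

CATEGORIES: tuple[str, ...] = ("X-pos", "Dist", "Upper", "Lower")
CATEGORY_DIMS: dict[str, int] = {"X-pos": 6, "Dist": 6, "Upper": 2, "Lower": 2}


@dataclass(frozen=True)
class ChannelSeries:
    """One named kinematic series: a value per frame of the source walk."""

    category: str
    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass
class ChannelSet:
    """An ordered collection of equal-length named channels."""

    channels: list[ChannelSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise AlignmentError(f"duplicate channel names: {names}")
        lengths = {len(c.values) for c in self.channels}
        if len(lengths) > 1:
            raise AlignmentError(f"channel length mismatch: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.channels)

    def __iter__(self):
        return iter(self.channels)

    @property
    def n_frames(self) -> int:
        return len(self.channels[0].values) if self.channels else 0

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one column per channel."""
        return pd.DataFrame({c.name: c.values for c in self.channels})

    def to_long_frame(self) -> pd.DataFrame:
        """Long table: (frame, category, channel, value)."""
        parts = [
            pd.DataFrame(
                {
                    "frame": np.arange(len(c.values)),
                    "category": c.category,
                    "channel": c.name,
                    "value": c.values,
                }
            )
            for c in self.channels
        ]
        return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def angle_at_vertex(a, b, c) -> float | np.ndarray:
    """Interior angle at vertex ``b`` between rays b→a and b→c, in degrees.

    Accepts single points (length-2) or stacked (n, 2) arrays and returns a
    scalar or an (n,) array accordingly; values lie in [0, 180].  Coincident
    points make a ray undefined and raise
    :class:`~gaitscore.errors.DegenerateGeometryError` (scalar input) or
    yield NaN (array input; callers interpolate).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    scalar = a.ndim == 1
    u = np.atleast_2d(a - b)
    v = np.atleast_2d(c - b)
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    degenerate = (nu == 0) | (nv == 0)
    if scalar and degenerate.any():
        raise DegenerateGeometryError("coincident points: angle undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang[degenerate] = np.nan
    return float(ang[0]) if scalar else ang


def _fill_degenerate(values: np.ndarray, what: str) -> np.ndarray:
    """Replace NaNs (degenerate frames) by interpolation from neighbours."""
    bad = ~np.isfinite(values)
    if not bad.any():
        return values
    if bad.all():
        raise DegenerateGeometryError(f"{what}: degenerate in every frame")
    logger.warning("%s: %d degenerate frame(s) interpolated (frames %s)",
                   what, bad.sum(), np.flatnonzero(bad)[:10].tolist())
    idx = np.arange(len(values))
    out = values.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], values[~bad])
    return out


def _trunk_length(seq: PoseSequence) -> np.ndarray:
    shoulder_mid = (seq.marker("left_shoulder") + seq.marker("right_shoulder")) / 2
    hip_mid = (seq.marker("left_hip") + seq.marker("right_hip")) / 2
    return np.linalg.norm(shoulder_mid - hip_mid, axis=1)


# ---------------------------------------------------------------------------
# Category extractors
# ---------------------------------------------------------------------------

_XPOS_MARKERS = ("left_hip", "right_hip", "left_wrist", "right_wrist",
                 "left_ankle", "right_ankle")


def extract_xpos(seq: PoseSequence, normalize_scale: bool = False) -> ChannelSet:
    """Raw x-positions of hips, wrists and ankles (6 channels, pixels)."""
    scale = _trunk_length(seq) if normalize_scale else None
    channels = []
    for marker in _XPOS_MARKERS:
        x = seq.marker(marker)[:, 0].copy()
        if scale is not None:
            x = x / scale
        channels.append(ChannelSeries("X-pos", f"x_{marker}", x))
    return ChannelSet(channels)


def extract_distances(seq: PoseSequence, normalize_scale: bool = False) -> ChannelSet:
    """The 6 inter-marker distances (pixels); neck = shoulder midpoint."""
    neck = (seq.marker("left_shoulder") + seq.marker("right_shoulder")) / 2
    pairs = [
        ("dist_ankle_ankle", seq.marker("left_ankle"), seq.marker("right_ankle")),
        ("dist_wrist_wrist", seq.marker("left_wrist"), seq.marker("right_wrist")),
        ("dist_left_hip_wrist", seq.marker("left_hip"), seq.marker("left_wrist")),
        ("dist_right_hip_wrist", seq.marker("right_hip"), seq.marker("right_wrist")),
        ("dist_neck_left_hip", neck, seq.marker("left_hip")),
        ("dist_neck_right_hip", neck, seq.marker("right_hip")),
    ]
    scale = _trunk_length(seq) if normalize_scale else None
    channels = []
    for name, p, q in pairs:
        d = np.linalg.norm(p - q, axis=1)
        if scale is not None:
            d = d / scale
        channels.append(ChannelSeries("Dist", name, d))
    return ChannelSet(channels)


def extract_upper_angles(seq: PoseSequence) -> ChannelSet:
    """Shoulder angles of the (wrist, shoulder, hip) triangle, per side."""
    channels = []
    for side in ("left", "right"):
        ang = angle_at_vertex(
            seq.marker(f"{side}_wrist"),
            seq.marker(f"{side}_shoulder"),
            seq.marker(f"{side}_hip"),
        )
        ang = _fill_degenerate(ang, f"upper angle ({side})")
        channels.append(ChannelSeries("Upper", f"angle_{side}_shoulder", ang))
    return ChannelSet(channels)


def extract_lower_angles(seq: PoseSequence) -> ChannelSet:
    """Hip angles subtended by the two ankles, at each hip."""
    channels = []
    for side in ("left", "right"):
        ang = angle_at_vertex(
            seq.marker("left_ankle"),
            seq.marker(f"{side}_hip"),
            seq.marker("right_ankle"),
        )
        ang = _fill_degenerate(ang, f"lower angle ({side})")
        channels.append(ChannelSeries("Lower", f"angle_{side}_hip", ang))
    return ChannelSet(channels)


_EXTRACTORS = {
    "X-pos": extract_xpos,
    "Dist": extract_distances,
    "Upper": extract_upper_angles,
    "Lower": extract_lower_angles,
}


def extract_category(seq: PoseSequence, category: str) -> ChannelSet:
    """Extract one named category's channels."""
    try:
        return _EXTRACTORS[category](seq)
    except KeyError:
        raise AlignmentError(
            f"unknown category {category!r}; expected one of {CATEGORIES}"
        ) from None


def extract_all(seq: PoseSequence) -> dict[str, ChannelSet]:
    """All four categories keyed by category name."""
    return {cat: extract_category(seq, cat) for cat in CATEGORIES}


def combine_channels(*sets: ChannelSet) -> ChannelSet:
    """Concatenate channel sets, preserving provenance; lengths must agree."""
    if not sets:
        raise AlignmentError("no channel sets to combine")
    lengths = {s.n_frames for s in sets}
    if len(lengths) > 1:
        raise AlignmentError(f"channel sets of different lengths: {sorted(lengths)}")
    return ChannelSet([c for s in sets for c in s.channels])


def category_combinations() -> list[tuple[str, ...]]:
    """The 15 non-empty category subsets, in a fixed canonical order."""
    combos = []
    for r in range(1, len(CATEGORIES) + 1):
        combos.extend(itertools.combinations(CATEGORIES, r))
    return combos
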