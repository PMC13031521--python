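"""COCO 17-keypoint conventions used throughout the package.

Coordinate convention (pinned once, used everywhere): image pixels with the
origin at the top-left corner, x increasing rightward, y increasing
*downward* — the convention of 2D pose estimators operating on video frames.
"""

from __future__ import annotations

# Canonical COCO keypoint order. All downstream marker references resolve
# through these names; never index keypoints by bare integers elsewhere.
COCO_KEYPOINTS: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

N_KEYPOINTS: int = len(COCO_KEYPOINTS)  # 17

KEYPOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(COCO_KEYPOINTS)}

#: left/right partner pairs, used when a half-turn mirrors the walker.
LR_PAIRS: tuple[tuple[str, str], ...] = (
    ("left_eye", "right_eye"),
    ("left_ear", "right_ear"),
    ("left_shoulder", "right_shoulder"),
    ("left_elbow", "right_elbow"),
    ("left_wrist", "right_wrist"),
    ("left_hip", "right_hip"),
    ("left_knee", "right_knee"),
    ("left_ankle", "right_ankle"),
)


def mirror_index_map() -> list[int]:
    """Index permutation that swaps every left keypoint with its right partner."""
    perm = list(range(N_KEYPOINTS))
    for left, right in LR_PAIRS:
        li, ri = KEYPOINT_INDEX[left], KEYPOINT_INDEX[right]
        perm[li], perm[ri] = ri, li
    return perm
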