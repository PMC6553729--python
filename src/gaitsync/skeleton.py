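"""Shared containers for 2D pose keypoints.

A *skeleton* is one person's 18 named body parts in one video frame, each an
(x, y) position in image pixel coordinates (y grows downward, the pose
estimator convention) with a detection confidence.  Undetected parts are
stored as NaN coordinates with zero confidence.  The 18-part layout is the
COCO ordering used by OpenPose-style estimators.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

PART_NAMES: tuple[str, ...] = (
    "nose",
    "neck",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
    "left_shoulder",
    "left_elbow",
    "left_wrist",
    "right_hip",
    "right_knee",
    "right_ankle",
    "left_hip",
    "left_knee",
    "left_ankle",
    "right_eye",
    "left_eye",
    "right_ear",
    "left_ear",
)
N_PARTS = len(PART_NAMES)  # 18
PART_INDEX = {name: i for i, name in enumerate(PART_NAMES)}

NOSE = PART_INDEX["nose"]
NECK = PART_INDEX["neck"]
RIGHT_ANKLE = PART_INDEX["right_ankle"]
LEFT_ANKLE = PART_INDEX["left_ankle"]

# BODY_25 index providing each of the 18 COCO parts (BODY_25 inserts mid-hip
# at index 8 and appends foot keypoints, which have no COCO counterpart).
BODY25_TO_COCO18 = (0, 1, 2, 3, 4, 5, 6, 7, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18)


@dataclass
class Skeleton:
    """One person's 18 keypoints in one frame.

    Parameters
    ----------
    xy : (18, 2) float array
        Pixel coordinates; NaN rows mark undetected parts.
    confidence : (18,) float array
        Detector confidence in [0, 1]; 0 for undetected parts.
    frame_index : int
        Source frame number.
    person_index : int
        Per-frame person slot assigned by the detector; *not* stable across
        frames (identity is established later by tracking).
    """

    xy: np.ndarray
    confidence: np.ndarray = None  # type: ignore[assignment]
    frame_index: int = 0
    person_index: int = 0

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (N_PARTS, 2):
            raise ValueError(f"xy must have shape ({N_PARTS}, 2), got {self.xy.shape}")
        if self.confidence is None:
            self.confidence = np.where(self.present, 1.0, 0.0)
        else:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != (N_PARTS,):
                raise ValueError(f"confidence must have shape ({N_PARTS},)")

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of detected parts."""
        return np.isfinite(self.xy).all(axis=1)

    @property
    def n_present(self) -> int:
        return int(self.present.sum())

    @property
    def height(self) -> float:
        """Vertical extent (max y − min y) over detected parts, in pixels."""
        y = self.xy[self.present, 1]
        if y.size == 0:
            return float("nan")
        return float(y.max() - y.min())

    @property
    def mean_ankle_y(self) -> float:
        """Mean image y of the two ankles (NaN if either is missing)."""
        return float(self.xy[[LEFT_ANKLE, RIGHT_ANKLE], 1].mean())

    def part(self, name: str) -> np.ndarray:
        return self.xy[PART_INDEX[name]]

    def translated(self, dx: float, dy: float) -> "Skeleton":
        return replace(self, xy=self.xy + np.array([dx, dy]))

    def scaled(self, s: float) -> "Skeleton":
        """Uniformly rescale about the image origin (camera zoom analogue)."""
        return replace(self, xy=self.xy * float(s))


@dataclass
class FramePoses:
    """All skeletons detected in one frame."""

    frame_index: int
    timestamp: float  # seconds
    skeletons: list[Skeleton] = field(default_factory=list)


def bounding_box(skeletons: Sequence[Skeleton]) -> tuple[float, float, float, float]:
    """Axis-aligned box (x_min, y_min, width, height) enclosing all present
    keypoints of the given skeletons."""
    pts = np.concatenate([s.xy[s.present] for s in skeletons], axis=0)
    if pts.size == 0:
        raise ValueError("no present keypoints to bound")
    x_min, y_min = pts.min(axis=0)
    x_max, y_max = pts.max(axis=0)
    return float(x_min), float(y_min), float(x_max - x_min), float(y_max - y_min)
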