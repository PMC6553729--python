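"""Frame-level detection of side-by-side walking pairs and segment assembly.

A candidate pair of skeletons is accepted in a frame when all of these hold:

* both skeletons are *complete*: at least 14 of the 18 parts detected, and
  both ankles among them;
* the bounding box around the pair has height:width aspect ratio between
  1:1 and 3:1 (side-by-side walkers, not a queue);
* the two skeletons' ankles are at similar image height — mean ankle y
  within 15% of the box height (both on the same ground plane);
* the box is taller than 120 px (enough spatial resolution);
* the taller:shorter skeleton height ratio is below 1.25 (two adults, not
  an adult-child pair).

Video is scanned at a subsampled 2 frames/s; accepted pairs persisting for a
minimum duration become segments.  Pairs that share a person with another
accepted pair for 3 or more consecutive subsampled frames are treated as a
group of 3+ walkers and excluded.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .skeleton import FramePoses, Skeleton, bounding_box

MIN_PARTS = 14
ASPECT_MIN = 1.0
ASPECT_MAX = 3.0
ANKLE_GAP_FRACTION = 0.15
MIN_BBOX_HEIGHT = 120.0
MAX_SIZE_RATIO = 1.25

REJECTION_REASONS = (
    "incomplete_skeleton",
    "aspect_ratio",
    "ankle_y_gap",
    "bbox_height",
    "size_ratio",
)


@dataclass
class PairDecision:
    person_indices: tuple[int, int]
    bbox: tuple[float, float, float, float] | None  # (x_min, y_min, w, h)
    accepted: bool
    rejection_reasons: list[str] = field(default_factory=list)
    frame_index: int = 0


@dataclass
class SegmentCandidate:
    start_frame: int  # original frame index, inclusive
    end_frame: int  # original frame index, inclusive
    pair: tuple[int, int]  # person indices (per-frame slots)
    member_indices: list[tuple[int, int]]  # per subsampled frame
    sampling_rate: float  # subsampled frames/second

    @property
    def n_frames(self) -> int:
        return len(self.member_indices)

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) / self.sampling_rate


def skeleton_complete(s: Skeleton) -> bool:
    """≥14 of 18 parts present, and both ankles among them."""
    present = s.present
    from .skeleton import LEFT_ANKLE, RIGHT_ANKLE

    return bool(present.sum() >= MIN_PARTS and present[LEFT_ANKLE] and present[RIGHT_ANKLE])


def check_pair(a: Skeleton, b: Skeleton) -> PairDecision:
    """Apply the four pair criteria; rejections are data, not errors."""
    idx = (a.person_index, b.person_index)
    if not (skeleton_complete(a) and skeleton_complete(b)):
        return PairDecision(idx, None, False, ["incomplete_skeleton"], a.frame_index)

    bbox = bounding_box([a, b])
    _, _, width, height = bbox
    reasons: list[str] = []

    aspect = height / width if width > 0 else np.inf
    if not (ASPECT_MIN <= aspect <= ASPECT_MAX):
        reasons.append("aspect_ratio")
    if abs(a.mean_ankle_y - b.mean_ankle_y) > ANKLE_GAP_FRACTION * height:
        reasons.append("ankle_y_gap")
    if not height > MIN_BBOX_HEIGHT:
        reasons.append("bbox_height")
    ha, hb = a.height, b.height
    if max(ha, hb) / min(ha, hb) >= MAX_SIZE_RATIO:
        reasons.append("size_ratio")

    return PairDecision(idx, bbox, not reasons, reasons, a.frame_index)


def subsample(frames: list[FramePoses], target_rate: float = 2.0) -> list[FramePoses]:
    """Nearest-frame decimation to ``target_rate`` frames/second.

    One frame is chosen per tick k/target_rate (k = 0, 1, ...) up to the
    last timestamp; timestamps are preserved.  Requires source rate >= the
    target rate.
    """
    if not frames:
        return []
    ts = np.array([f.timestamp for f in frames])
    if len(frames) > 1:
        src_rate = 1.0 / np.median(np.diff(ts))
        if src_rate < target_rate - 1e-9:
            raise ValueError(f"source rate {src_rate:.3f} fps is below target {target_rate} fps")
    n_ticks = int(np.floor(ts[-1] * target_rate + 1e-9)) + 1
    picks = [int(np.argmin(np.abs(ts - k / target_rate))) for k in range(n_ticks)]
    return [frames[i] for i in picks]


def detect_pairs(frames: list[FramePoses]) -> list[list[PairDecision]]:
    """Evaluate every skeleton pair in every frame (accepted and rejected)."""
    out = []
    for fp in frames:
        decisions = [check_pair(a, b) for a, b in itertools.combinations(fp.skeletons, 2)]
        out.append(decisions)
    return out


def find_segments(
    detections: list[list[PairDecision]],
    sampling_rate: float = 2.0,
    min_duration: float = 2.0,
    group_window: int = 3,
) -> list[SegmentCandidate]:
    """Assemble maximal runs of persistently accepted pairs into segments.

    ``detections`` holds per-(subsampled-)frame pair decisions.  A pair that
    shares a person with another accepted pair for ``group_window`` or more
    consecutive frames suggests a group of 3+ walkers; both pairs are
    excluded from those frames.  Surviving runs whose span
    (n_frames − 1)/rate meets ``min_duration`` become segments.
    """
    n = len(detections)
    accepted: list[set[tuple[int, int]]] = []
    frame_ids: list[int] = []
    for frame_decisions in detections:
        acc = {tuple(sorted(d.person_indices)) for d in frame_decisions if d.accepted}
        accepted.append(acc)
        frame_ids.append(frame_decisions[0].frame_index if frame_decisions else -1)

    # group exclusion: runs of co-present pair-of-pairs sharing a member
    drop: list[set[tuple[int, int]]] = [set() for _ in range(n)]
    conflict_keys = set()
    for acc in accepted:
        for p, q in itertools.combinations(sorted(acc), 2):
            if set(p) & set(q):
                conflict_keys.add((p, q))
    for p, q in conflict_keys:
        run = 0
        for i in range(n + 1):
            here = i < n and p in accepted[i] and q in accepted[i]
            if here:
                run += 1
            else:
                if run >= group_window:
                    for j in range(i - run, i):
                        drop[j].update((p, q))
                run = 0

    surviving = [acc - dr for acc, dr in zip(accepted, drop)]

    segments: list[SegmentCandidate] = []
    all_pairs = set().union(*surviving) if surviving else set()
    for pair in sorted(all_pairs):
        run_start = None
        for i in range(n + 1):
            here = i < n and pair in surviving[i]
            if here and run_start is None:
                run_start = i
            elif not here and run_start is not None:
                length = i - run_start
                if (length - 1) / sampling_rate >= min_duration:
                    segments.append(
                        SegmentCandidate(
                            start_frame=frame_ids[run_start],
                            end_frame=frame_ids[i - 1],
                            pair=pair,
                            member_indices=[pair] * length,
                            sampling_rate=sampling_rate,
                        )
                    )
                run_start = None
    segments.sort(key=lambda s: (s.start_frame, s.pair))
    return segments


def detection_audit(detections: list[list[PairDecision]]) -> pd.DataFrame:
    """One row per rejected pair with its reasons (audit log)."""
    rows = [
        {
            "frame": d.frame_index,
            "person_a": d.person_indices[0],
            "person_b": d.person_indices[1],
            "reasons": ";".join(d.rejection_reasons),
        }
        for frame_decisions in detections
        for d in frame_decisions
        if not d.accepted
    ]
    return pd.DataFrame(rows, columns=["frame", "person_a", "person_b", "reasons"])
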