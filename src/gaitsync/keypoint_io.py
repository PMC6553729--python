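"""Read and write per-frame pose keypoints and tabular results.

The on-disk frame format is the OpenPose JSON dialect: one file per frame
holding a top-level ``"people"`` array whose entries carry a flat
``"pose_keypoints_2d"`` list of (x, y, confidence) triplets.  Both the
18-part COCO layout and the 25-part BODY_25 layout are accepted on read;
BODY_25 is mapped down to the 18 shared parts.  A keypoint triplet of
``(0, 0, 0)`` or zero confidence means "not detected", never "at the
origin".
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .skeleton import BODY25_TO_COCO18, N_PARTS, PART_NAMES, FramePoses, Skeleton

_FRAME_RE = re.compile(r"(\d+)(?!.*\d)")  # last run of digits in the stem


@dataclass
class FrameSequence:
    """Ordered frames plus bookkeeping about gaps in the frame numbering."""

    frames: list[FramePoses]
    fps: float
    missing_frames: list[int] = field(default_factory=list)

    def __iter__(self):
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


def _skeleton_from_flat(values: Sequence[float], frame_index: int, person_index: int) -> Skeleton:
    arr = np.asarray(values, dtype=float)
    if arr.size == 3 * N_PARTS:
        triplets = arr.reshape(N_PARTS, 3)
    elif arr.size == 3 * 25:
        triplets = arr.reshape(25, 3)[list(BODY25_TO_COCO18)]
    else:
        raise ValueError(
            f"pose_keypoints_2d has {arr.size} values; expected {3 * N_PARTS} (COCO) or 75 (BODY_25)"
        )
    xy = triplets[:, :2].copy()
    conf = triplets[:, 2].copy()
    missing = (conf <= 0) | ((triplets[:, 0] == 0.0) & (triplets[:, 1] == 0.0))
    xy[missing] = np.nan
    conf[missing] = 0.0
    return Skeleton(xy=xy, confidence=conf, frame_index=frame_index, person_index=person_index)


def _flat_from_skeleton(s: Skeleton) -> list[float]:
    out = np.zeros((N_PARTS, 3))
    p = s.present
    out[p, :2] = s.xy[p]
    out[p, 2] = s.confidence[p]
    return [float(v) for v in out.ravel()]


def frame_filename(frame_index: int, prefix: str = "frame") -> str:
    return f"{prefix}_{frame_index:012d}_keypoints.json"


def read_openpose_frames(path: str | Path, fps: float) -> FrameSequence:
    """Read a directory of per-frame OpenPose JSON files.

    Frames are ordered by the frame index parsed from the file name (the
    last run of digits in the stem).  Gaps in the numbering are recorded in
    ``missing_frames`` — they are never silently filled.  Malformed JSON is
    a hard error naming the offending file.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    directory = Path(path)
    files = sorted(directory.glob("*.json"))
    if not files:
        raise FileNotFoundError(f"no JSON frame files in {directory}")
    indexed: list[tuple[int, Path]] = []
    for f in files:
        m = _FRAME_RE.search(f.stem)
        if m is None:
            raise ValueError(f"cannot parse a frame index from file name {f.name}")
        indexed.append((int(m.group(1)), f))
    indexed.sort(key=lambda t: t[0])

    frames: list[FramePoses] = []
    for idx, f in indexed:
        try:
            payload = json.loads(f.read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed JSON in {f}: {exc}") from exc
        people = payload.get("people", [])
        skels = [
            _skeleton_from_flat(person["pose_keypoints_2d"], idx, k)
            for k, person in enumerate(people)
        ]
        frames.append(FramePoses(frame_index=idx, timestamp=idx / fps, skeletons=skels))

    present = {fp.frame_index for fp in frames}
    lo, hi = min(present), max(present)
    missing = [i for i in range(lo, hi + 1) if i not in present]
    return FrameSequence(frames=frames, fps=fps, missing_frames=missing)


def write_openpose_frames(frames: Iterable[FramePoses], out_dir: str | Path, prefix: str = "frame") -> list[Path]:
    """Write frames as one OpenPose-dialect JSON file per frame."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for fp in frames:
        payload = {
            "version": 1.3,
            "people": [{"person_id": [s.person_index], "pose_keypoints_2d": _flat_from_skeleton(s)} for s in fp.skeletons],
        }
        dest = out / frame_filename(fp.frame_index, prefix)
        dest.write_text(json.dumps(payload))
        written.append(dest)
    return written


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    """Per-segment metadata: segment_id, fps, hand_contact (yes/no -> bool)."""
    df = pd.read_csv(path)
    required = {"segment_id", "fps", "hand_contact"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata CSV must have columns {sorted(required)}")
    df = df.copy()
    df["hand_contact"] = (
        df["hand_contact"].astype(str).str.strip().str.lower().map({"yes": True, "no": False, "true": True, "false": False})
    )
    if df["hand_contact"].isna().any():
        raise ValueError("hand_contact must be yes/no")
    return df


def tracked_to_frame(xy: np.ndarray, frame_indices: np.ndarray, segment_id: str = "") -> pd.DataFrame:
    """Long-format table (segment, frame, walker, part, x, y) of a tracked pair.

    ``xy`` has shape (2, n_frames, 18, 2); gap frames are NaN rows.
    """
    n_walkers, n_frames, _, _ = xy.shape
    rows = {
        "segment_id": np.repeat(segment_id, n_walkers * n_frames * N_PARTS),
        "frame": np.tile(np.repeat(frame_indices, N_PARTS), n_walkers),
        "walker": np.repeat(np.arange(1, n_walkers + 1), n_frames * N_PARTS),
        "part": np.tile(list(PART_NAMES), n_walkers * n_frames),
        "x": xy[..., 0].ravel(),
        "y": xy[..., 1].ravel(),
    }
    return pd.DataFrame(rows)


def phase_results_to_frame(results: Sequence) -> pd.DataFrame:
    """One row per analyzed pair (see phase_pipeline.PhaseResult)."""
    rows = []
    for r in results:
        rows.append(
            {
                "segment_id": r.segment_id,
                "mean_rel_phase": r.mean_rel_phase,
                "rel_phase_variance": r.rel_phase_variance,
                "cadence1": r.cadence1.steps_per_s,
                "cadence2": r.cadence2.steps_per_s,
                "cadence1_confident": r.cadence1.confident,
                "cadence2_confident": r.cadence2.confident,
                "duration_s": r.duration_s,
                "frac_interpolated": r.quality.get("frac_interpolated", np.nan),
                "frac_outlier_replaced": r.quality.get("frac_outlier_replaced", np.nan),
            }
        )
    return pd.DataFrame(rows)
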