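"""Frame-to-frame identity tracking of a walker pair.

Pose estimators assign person slots per frame with no identity continuity,
so the pair found in the first frame must be followed through the segment.
The association cost between a skeleton in frame j and one in frame j+1 is
the mean Euclidean keypoint displacement

    D = (1/n) * sum_i sqrt((x_i,j - x_i,j+1)^2 + (y_i,j - y_i,j+1)^2)

over the n keypoints present in both frames.  Two modes are provided:

* ``joint`` (default): the two tracked identities are assigned to candidate
  skeletons by a one-to-one assignment minimizing total cost (optimal for a
  2 x k problem), which removes the identity-switch failure mode of
  independent greedy matching;
* ``greedy``: each identity independently takes its nearest candidate, the
  classic behaviour whose conflicts are recorded as switch suspects.

Assignments whose cost exceeds a max-jump threshold (a fraction of skeleton
height per elapsed frame) leave a gap instead; gaps are later filled by the
interpolation stage of the phase pipeline.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .skeleton import N_PARTS, FramePoses, Skeleton

_BIG = 1e12


@dataclass
class TrackedSegment:
    """Two identity-consistent keypoint time series at the full frame rate."""

    xy: np.ndarray  # (2, n_frames, 18, 2); NaN where the walker is unmatched
    fps: float
    frame_indices: np.ndarray  # (n_frames,)
    assigned_person: np.ndarray  # (2, n_frames) per-frame slot, -1 = gap
    provenance: str = ""
    mode: str = "joint"
    truncated: bool = False
    quality: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.xy.shape[1]

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) / self.fps

    @property
    def gap_mask(self) -> np.ndarray:
        return self.assigned_person < 0


def skeleton_distance(s_a: Skeleton, s_b: Skeleton) -> float:
    """Mean Euclidean displacement over keypoints present in both skeletons.

    Returns +inf when no keypoint is shared (non-matchable).
    """
    shared = s_a.present & s_b.present
    if not shared.any():
        return np.inf
    d = np.linalg.norm(s_a.xy[shared] - s_b.xy[shared], axis=1)
    return float(d.mean())


def assign_pair(costs: np.ndarray, thresholds: np.ndarray, gap_costs: np.ndarray | None = None) -> list[int]:
    """Optimal one-to-one assignment of 2 identities to k candidates.

    ``costs`` is (2, k); ``thresholds`` gives each identity's max acceptable
    cost.  Returns a candidate index per identity, or -1 for a gap.  A gap
    is modelled as a per-identity dummy candidate priced at ``gap_costs``
    (default: the thresholds), so the solution is the exact minimum over all
    one-to-one matchings with optional non-assignment.  Pricing the gap
    below a stale identity's widened acceptance threshold prevents an
    identity that has been missing for a while from stealing the other
    identity's well-matched skeleton.
    """
    if gap_costs is None:
        gap_costs = thresholds
    k = costs.shape[1]
    mat = np.full((2, k + 2), _BIG)
    mat[:, :k] = np.minimum(costs, _BIG)
    mat[0, k] = gap_costs[0]
    mat[1, k + 1] = gap_costs[1]
    rows, cols = linear_sum_assignment(mat)
    out = [-1, -1]
    for r, c in zip(rows, cols):
        if c < k and mat[r, c] <= thresholds[r]:
            out[r] = int(c)
    return out


def track_pair(
    frames: list[FramePoses],
    seed_pair,
    fps: float,
    mode: str = "joint",
    max_jump_factor: float = 0.5,
    gap_tolerance_s: float = 0.25,
    provenance: str = "",
) -> TrackedSegment:
    """Track the seeded pair through full-rate frames.

    ``seed_pair`` is a PairDecision or an (index_a, index_b) tuple into the
    first frame's skeleton list; it must identify an accepted pair there.
    When both identities stay unmatched for more than ``gap_tolerance_s``
    the segment is truncated at the last matched frame and flagged.
    """
    if mode not in ("joint", "greedy"):
        raise ValueError("mode must be 'joint' or 'greedy'")
    if not frames:
        raise ValueError("no frames to track")
    idx = getattr(seed_pair, "person_indices", seed_pair)
    ia, ib = int(idx[0]), int(idx[1])

    n = len(frames)
    xy = np.full((2, n, N_PARTS, 2), np.nan)
    assigned = np.full((2, n), -1, dtype=int)
    last: list[Skeleton] = [frames[0].skeletons[ia], frames[0].skeletons[ib]]
    last_i = [0, 0]
    for w, s in enumerate(last):
        xy[w, 0] = s.xy
        assigned[w, 0] = s.person_index

    switch_suspects = 0
    gap_run = 0
    truncated = False
    end = n
    gap_tol = max(1, int(round(gap_tolerance_s * fps)))

    for i in range(1, n):
        cands = frames[i].skeletons
        k = len(cands)
        thresholds = np.array(
            [max_jump_factor * last[w].height * (i - last_i[w]) for w in range(2)]
        )
        if k == 0:
            choice = [-1, -1]
        else:
            costs = np.array([[skeleton_distance(last[w], c) for c in cands] for w in range(2)])
            if mode == "joint":
                base = np.array([max_jump_factor * last[w].height for w in range(2)])
                choice = assign_pair(costs, thresholds, gap_costs=base)
            else:
                choice = [-1, -1]
                for w in range(2):
                    c = int(np.argmin(costs[w]))
                    if costs[w, c] <= thresholds[w]:
                        choice[w] = c
                if choice[0] >= 0 and choice[0] == choice[1]:
                    switch_suspects += 1

        for w in range(2):
            c = choice[w]
            if c >= 0:
                last[w] = cands[c]
                last_i[w] = i
                xy[w, i] = cands[c].xy
                assigned[w, i] = cands[c].person_index

        if choice[0] < 0 and choice[1] < 0:
            gap_run += 1
            if gap_run > gap_tol:
                end = max(last_i) + 1
                truncated = True
                break
        else:
            gap_run = 0

    xy = xy[:, :end]
    assigned = assigned[:, :end]
    frame_indices = np.array([f.frame_index for f in frames[:end]])
    gap_frac = [float((assigned[w] < 0).mean()) for w in range(2)]
    return TrackedSegment(
        xy=xy,
        fps=fps,
        frame_indices=frame_indices,
        assigned_person=assigned,
        provenance=provenance,
        mode=mode,
        truncated=truncated,
        quality={
            "gap_fraction_walker1": gap_frac[0],
            "gap_fraction_walker2": gap_frac[1],
            "switch_suspects": switch_suspects,
        },
    )
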