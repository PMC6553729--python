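"""Synthetic keypoint scenes of walking pairs with known ground truth.

The generator emulates the signal structure the downstream analysis
assumes: each walker's vertical ankle motion is sinusoidal, the left and
right ankles oscillate in anti-phase (one displacement cycle = two steps),
and the second walker's gait leads the first by a controllable relative
phase.  The rest of the 18-part skeleton is a fixed anatomical template
carried along with the ankles, which is all the completeness and
bounding-box rules ever look at.  Camera drift (additive or zoom trends on
every keypoint), Gaussian pixel noise, i.i.d. missing keypoints, burst
occlusion, per-frame shuffling of person slots and distractor skeletons can
be layered on top — always *after* the ground truth is captured.

Image coordinates are y-down (larger y = lower in the frame), the pose
estimator convention.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .keypoint_io import write_openpose_frames
from .skeleton import LEFT_ANKLE, N_PARTS, PART_NAMES, RIGHT_ANKLE, FramePoses, Skeleton
from .validation import FootStrikeLabels

TWO_PI = 2.0 * math.pi

# Part layout as (x, y) offsets in fractions of walker height; x from the
# body midline, y measured *up* from the ground (converted to image-y later).
_TEMPLATE = {
    "nose": (0.00, 0.97),
    "neck": (0.00, 0.85),
    "right_shoulder": (0.12, 0.82),
    "right_elbow": (0.15, 0.65),
    "right_wrist": (0.15, 0.45),
    "left_shoulder": (-0.12, 0.82),
    "left_elbow": (-0.15, 0.65),
    "left_wrist": (-0.15, 0.45),
    "right_hip": (0.07, 0.52),
    "right_knee": (0.08, 0.27),
    "right_ankle": (0.09, 0.00),
    "left_hip": (-0.07, 0.52),
    "left_knee": (-0.08, 0.27),
    "left_ankle": (-0.09, 0.00),
    "right_eye": (0.03, 0.99),
    "left_eye": (-0.03, 0.99),
    "right_ear": (0.05, 0.96),
    "left_ear": (-0.05, 0.96),
}
_TEMPLATE_XY = np.array([_TEMPLATE[name] for name in PART_NAMES])  # (18, 2)


@dataclass(frozen=True)
class Drift:
    """Slow camera trend applied to every keypoint.

    kinds: ``none``; ``linear`` — add magnitude·t pixels to x and y
    (camera pan); ``sway`` — sinusoidal offset of amplitude ``magnitude``
    pixels at 0.1 Hz (handheld wobble); ``scale`` — multiply all
    coordinates by (1 + magnitude·t) about the image origin (zoom),
    magnitude in 1/s.
    """

    kind: str = "none"
    magnitude: float = 0.0

    def apply(self, xy: np.ndarray, t: np.ndarray) -> np.ndarray:
        """xy: (n_frames, ..., 2); t: (n_frames,) seconds."""
        if self.kind == "none" or self.magnitude == 0.0:
            return xy
        shape = (t.size,) + (1,) * (xy.ndim - 1)
        if self.kind == "linear":
            return xy + (self.magnitude * t).reshape(shape)
        if self.kind == "sway":
            return xy + (self.magnitude * np.sin(TWO_PI * 0.1 * t)).reshape(shape)
        if self.kind == "scale":
            return xy * (1.0 + self.magnitude * t).reshape(shape)
        raise ValueError(f"unknown drift kind {self.kind!r}")


@dataclass(frozen=True)
class GaitParams:
    """Scene parameters; defaults are the study conditions the generator
    emulates (typical urban cadence ~1.85 steps/s, adult-height skeletons,
    side-by-side spacing that satisfies the pair criteria)."""

    fps: float = 30.0
    duration: float = 5.0  # seconds
    step_frequency: float = 1.85  # steps/second; displacement cycles at half this
    relative_phase: float = 0.0  # radians, walker2 minus walker1, in (−π, π]
    amplitude: float = 15.0  # pixels of vertical ankle oscillation
    walker_height: float = 300.0  # pixels
    base_position: tuple = ((300.0, 400.0), (460.0, 400.0))  # ankle-level (x, y) per walker
    base_velocity: tuple = ((0.0, 0.0), (0.0, 0.0))  # pixels/second per walker
    drift: Drift = field(default_factory=Drift)
    noise_sd: float = 0.0  # pixels
    missing_prob: float = 0.0  # per keypoint per frame
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.step_frequency <= 0:
            raise ValueError("step_frequency must be positive")
        if not (0.0 <= self.missing_prob < 1.0):
            raise ValueError("missing_prob must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        wrapped = math.pi - (math.pi - self.relative_phase) % TWO_PI
        object.__setattr__(self, "relative_phase", wrapped)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class SyntheticGroundTruth:
    true_relative_phase: float  # radians, walker2 minus walker1
    true_cadence: tuple  # steps/second per walker
    foot_strike_times: dict  # walker -> {"left": [...], "right": [...]} seconds
    identity_map: np.ndarray  # (n_frames, 2) per-frame person slot of each walker; -1 = absent
    phase0: float = 0.0  # walker1's displacement phase at t = 0


def template_skeleton(
    height: float,
    base_xy: tuple[float, float],
    frame_index: int = 0,
    person_index: int = 0,
    drop_parts: tuple = (),
) -> Skeleton:
    """A static skeleton at the template pose (fixture helper)."""
    xy = _skeleton_xy(height, np.asarray(base_xy, float))
    for name in drop_parts:
        xy[PART_NAMES.index(name)] = np.nan
    return Skeleton(xy=xy, frame_index=frame_index, person_index=person_index)


def _skeleton_xy(height: float, base_xy: np.ndarray) -> np.ndarray:
    xy = np.empty((N_PARTS, 2))
    xy[:, 0] = base_xy[0] + _TEMPLATE_XY[:, 0] * height
    xy[:, 1] = base_xy[1] - _TEMPLATE_XY[:, 1] * height  # image y grows downward
    return xy


def generate_walker(
    params: GaitParams,
    phase0: float,
    base: tuple[float, float] | None = None,
    velocity: tuple[float, float] = (0.0, 0.0),
    height: float | None = None,
) -> np.ndarray:
    """Noise-free keypoint trajectory (n_frames, 18, 2) of one walker.

    Left ankle: y(t) = y0 + A·sin(2π·(f/2)·t + phase0); the right ankle is
    the same oscillation shifted by π, so the left−right displacement is a
    sinusoid at half the step frequency.  All other parts ride at fixed
    anatomical offsets; the camera drift trend is applied to every part.
    """
    base = np.asarray(base if base is not None else params.base_position[0], float)
    h = params.walker_height if height is None else height
    t = params.times
    centers = base[None, :] + np.asarray(velocity, float)[None, :] * t[:, None]

    xy = np.empty((params.n_frames, N_PARTS, 2))
    xy[:, :, 0] = centers[:, 0:1] + _TEMPLATE_XY[:, 0][None, :] * h
    xy[:, :, 1] = centers[:, 1:2] - _TEMPLATE_XY[:, 1][None, :] * h

    theta = TWO_PI * (params.step_frequency / 2.0) * t + phase0
    osc = (params.amplitude * h / params.walker_height) * np.sin(theta)
    xy[:, LEFT_ANKLE, 1] += osc
    xy[:, RIGHT_ANKLE, 1] -= osc  # sin(theta + π) = −sin(theta)
    return params.drift.apply(xy, t)


def _strike_times(params: GaitParams, phase0: float, target: float) -> list[float]:
    """Times in [0, duration] where the gait phase hits ``target`` (mod 2π)."""
    f_c = params.step_frequency / 2.0
    out = []
    k = math.ceil((phase0 - target) / TWO_PI - 1e-12)
    while True:
        t = (target - phase0 + TWO_PI * k) / (TWO_PI * f_c)
        if t > params.duration + 1e-12:
            break
        if t >= -1e-12:
            out.append(max(t, 0.0))
        k += 1
    return out


_DISTRACTOR_SPECS = {
    # child-sized companion: fails the adult size-ratio rule
    "child": dict(height_frac=0.55, offset=(360.0, 0.0), drop=()),
    # small far-away person higher in the frame: fails the ankle-height rule
    "distant": dict(height_frac=0.30, offset=(520.0, -180.0), drop=()),
    # heavily occluded skeleton: fails the completeness rule
    "partial": dict(
        height_frac=1.0,
        offset=(-260.0, 0.0),
        drop=("left_ankle", "right_wrist", "left_wrist", "right_elbow", "left_elbow", "nose", "right_eye", "left_eye"),
    ),
}


def generate_pair_scene(
    params: GaitParams,
    distractors: tuple = (),
    shuffle: bool = False,
    occlusion: dict | None = None,
) -> tuple[list[FramePoses], SyntheticGroundTruth]:
    """Two side-by-side walkers (plus optional distractors) with ground truth.

    Walker 2's gait phase leads walker 1's by ``params.relative_phase``.
    Noise, missingness, occlusion and slot shuffling are applied after the
    ground truth is captured.  ``distractors`` draws from
    {"child", "distant", "partial"}; ``occlusion`` is
    {"walker": 0|1, "start_frame": i, "n_frames": m} and removes that
    walker's skeleton entirely from those frames (burst occlusion).
    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    phase0 = float(rng.uniform(-math.pi, math.pi))
    phase_w2 = phase0 + params.relative_phase

    trajs = [
        generate_walker(params, phase0, base=params.base_position[0], velocity=params.base_velocity[0]),
        generate_walker(params, phase_w2, base=params.base_position[1], velocity=params.base_velocity[1]),
    ]
    truth = SyntheticGroundTruth(
        true_relative_phase=params.relative_phase,
        true_cadence=(params.step_frequency, params.step_frequency),
        foot_strike_times={
            w: {
                "left": _strike_times(params, p0, math.pi / 2.0),
                "right": _strike_times(params, p0, -math.pi / 2.0),
            }
            for w, p0 in ((0, phase0), (1, phase_w2))
        },
        identity_map=np.zeros((params.n_frames, 2), dtype=int),
        phase0=phase0,
    )

    for name in distractors:
        spec = _DISTRACTOR_SPECS[name]
        h = params.walker_height * spec["height_frac"]
        base = (
            params.base_position[0][0] + spec["offset"][0],
            params.base_position[0][1] + spec["offset"][1],
        )
        traj = generate_walker(
            params, float(rng.uniform(-math.pi, math.pi)), base=base, height=h
        )
        for part in spec["drop"]:
            traj[:, PART_NAMES.index(part), :] = np.nan
        trajs.append(traj)

    n = params.n_frames
    # perturbations drawn in a fixed order so scenes differ only where asked
    noisy = []
    for traj in trajs:
        noise = rng.normal(0.0, params.noise_sd, size=traj.shape) if params.noise_sd > 0 else 0.0
        miss = rng.random(size=(n, N_PARTS)) < params.missing_prob if params.missing_prob > 0 else None
        out = traj + noise
        if miss is not None:
            out = out.copy()
            out[miss] = np.nan
        noisy.append(out)

    occluded = set()
    if occlusion is not None:
        w = occlusion["walker"]
        for i in range(occlusion["start_frame"], occlusion["start_frame"] + occlusion["n_frames"]):
            occluded.add((w, i))

    frames: list[FramePoses] = []
    for i in range(n):
        members = [k for k in range(len(noisy)) if (k, i) not in occluded]
        order = list(rng.permutation(len(members))) if shuffle else list(range(len(members)))
        slots = [-1] * len(noisy)
        skels = [None] * len(members)
        for pos, which in zip(order, members):
            skels[pos] = Skeleton(xy=noisy[which][i].copy(), frame_index=i, person_index=pos)
            slots[which] = pos
        for w in range(2):
            truth.identity_map[i, w] = slots[w]
        frames.append(FramePoses(frame_index=i, timestamp=i / params.fps, skeletons=skels))
    return frames, truth


def generate_foot_strikes(truth: SyntheticGroundTruth, segment_id: str = "synthetic", labeler: str = "generator") -> FootStrikeLabels:
    """Ground-truth strike times in the foot-strike-label container, as a
    stand-in for a human annotator."""
    strikes = {
        w: {"left": list(d["left"]), "right": list(d["right"])}
        for w, d in truth.foot_strike_times.items()
    }
    return FootStrikeLabels(strikes=strikes, segment_id=segment_id, labeler=labeler)


def sample_population_params(
    n_pairs: int,
    rng: np.random.Generator,
    cadence_mean: float = 1.85,
    cadence_sd: float = 0.32,
    phase_means=(0.0, math.pi),
    phase_kappas=(4.0, 4.0),
    phase_weights=(0.5, 0.5),
    **overrides,
) -> list[GaitParams]:
    """Draw per-pair scene parameters matching a naturalistic cohort:
    cadence ~ N(1.85, 0.32) steps/s clipped to [1.0, 2.5] and relative
    phase from an in-phase/anti-phase von Mises mixture."""
    from .circular_stats import sample_vm_mixture

    cadences = np.clip(rng.normal(cadence_mean, cadence_sd, size=n_pairs), 1.0, 2.5)
    phases = sample_vm_mixture(n_pairs, phase_means, phase_kappas, phase_weights, rng)
    return [
        replace(
            GaitParams(seed=int(rng.integers(2**31))),
            step_frequency=float(c),
            relative_phase=float(p),
            **overrides,
        )
        for c, p in zip(cadences, phases)
    ]


def write_scene(
    frames: list[FramePoses],
    truth: SyntheticGroundTruth,
    out_dir: str | Path,
    params: GaitParams | None = None,
) -> None:
    """Write a scene as OpenPose JSON frames plus a ground-truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_openpose_frames(frames, out / "frames")

    rows = []
    for i, fp in enumerate(frames):
        for w in range(2):
            slot = truth.identity_map[i, w]
            if slot < 0:
                continue
            s = fp.skeletons[slot]
            for p, name in enumerate(PART_NAMES):
                rows.append((fp.frame_index, w + 1, name, s.xy[p, 0], s.xy[p, 1]))
    df = pd.DataFrame(rows, columns=["frame", "walker", "part", "x", "y"])
    with open(out / "ground_truth.csv", "w") as fh:
        fh.write(f"# true_relative_phase={truth.true_relative_phase!r}\n")
        fh.write(f"# true_cadence={truth.true_cadence!r}\n")
        if params is not None:
            fh.write(f"# fps={params.fps!r} duration={params.duration!r} seed={params.seed!r}\n")
        df.to_csv(fh, index=False)
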