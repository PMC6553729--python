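"""Ground-truth walking-angle signals from foot-strike labels.

Foot strikes are the most salient gait events to annotate by eye, and the
walking angle is extremal exactly when a foot strikes the ground.  A
"piecemeal sinewave" is therefore built from strike labels — −1 at every
left strike, +1 at every right strike, half-cosine arcs in between — and
pushed through the same displacement analysis as the pose-derived signal.
Agreement between the two routes is summarized by R².
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from . import circular_stats as cs
from . import phase_pipeline as pp


@dataclass
class FootStrikeLabels:
    """Per-walker left/right foot-strike times, in seconds.

    ``strikes`` maps walker index (0, 1) to {"left": [...], "right": [...]}.
    """

    strikes: dict
    segment_id: str = ""
    labeler: str = ""

    def events(self, walker: int) -> list[tuple[float, float]]:
        """Time-sorted (time, value) events; −1 for left, +1 for right."""
        d = self.strikes[walker]
        ev = [(float(t), -1.0) for t in d["left"]] + [(float(t), +1.0) for t in d["right"]]
        ev.sort()
        return ev


def _check_alternation(events: list[tuple[float, float]], walker: int) -> None:
    for (t0, v0), (t1, v1) in zip(events, events[1:]):
        if v0 == v1:
            side = "left" if v1 < 0 else "right"
            raise ValueError(
                f"walker {walker}: consecutive {side} strikes at {t0:.3f} s and {t1:.3f} s — sides must alternate"
            )


def strikes_to_signal(
    labels: FootStrikeLabels,
    fs: float,
    span: float,
    mode: str = "halfcos",
) -> tuple[np.ndarray, dict]:
    """Sample the ±1 piecemeal sinewave per walker at ``fs`` over ``span`` s.

    Between consecutive strikes at t_k < t_{k+1} with values v_k = −v_{k+1}
    the signal follows the half-cosine v_k·cos(π·(t − t_k)/(t_{k+1} − t_k)),
    the smooth oscillation that is exactly ±1 at the strikes; ``mode
    ="linear"`` uses straight lines instead.  Before the first and after
    the last strike the signal is held constant.
    """
    if mode not in ("halfcos", "linear"):
        raise ValueError("mode must be 'halfcos' or 'linear'")
    t = np.arange(int(round(span * fs))) / fs
    out = {}
    for walker in sorted(labels.strikes):
        events = labels.events(walker)
        if len(events) < 2:
            raise ValueError(f"walker {walker}: need at least 2 strikes")
        _check_alternation(events, walker)
        v = np.empty_like(t)
        v[t <= events[0][0]] = events[0][1]
        v[t >= events[-1][0]] = events[-1][1]
        for (t0, v0), (t1, v1) in zip(events, events[1:]):
            m = (t >= t0) & (t < t1)
            if mode == "halfcos":
                v[m] = v0 * np.cos(np.pi * (t[m] - t0) / (t1 - t0))
            else:
                v[m] = v0 + (v1 - v0) * (t[m] - t0) / (t1 - t0)
        out[walker] = v
    return t, out


def label_phase_analysis(
    labels: FootStrikeLabels,
    fs: float,
    span: float,
    edge_margin_s: float = 0.25,
    mode: str = "halfcos",
):
    """Run the displacement-stage analysis on label-derived signals.

    Returns (mean relative phase walker2 − walker1, cadence per walker).
    """
    _, signals = strikes_to_signal(labels, fs, span, mode=mode)
    phases = {}
    cadences = {}
    for walker, v in signals.items():
        s = v - v.mean()
        s = pp.lowpass(s, fs)
        s = s - s.mean()
        phases[walker] = pp.hilbert_phase(s)
        cadences[walker] = pp.walking_frequency(s, fs)
    rel = pp.relative_phase(phases[1], phases[0])
    margin = int(round(edge_margin_s * fs))
    core = rel[margin : rel.size - margin] if margin > 0 else rel
    return cs.circular_mean(core), (cadences[0], cadences[1])


def agreement(estimates_a, estimates_b, circular: bool = False) -> float:
    """R² agreement between paired per-segment scalars.

    For circular quantities, each b is first re-centered to the 2π branch
    nearest its reference a (so a pair (−3.1, 3.1) is 0.083 rad apart, not
    6.2); an ordinary linear-fit R² is then computed.
    """
    a = np.asarray(estimates_a, dtype=float)
    b = np.asarray(estimates_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-D vectors required")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(a) == 0:
        raise ValueError("zero variance in reference — R² undefined")
    if circular:
        b = a + cs.wrap_angle(b - a)
    fit = linregress(a, b)
    return float(fit.rvalue**2)


def read_labels_csv(path) -> list[FootStrikeLabels]:
    """Labels CSV: segment_id, walker (1/2), side (left/right), time_s, labeler."""
    df = pd.read_csv(path)
    required = {"segment_id", "walker", "side", "time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"labels CSV must have columns {sorted(required)}")
    out = []
    for (seg, labeler), grp in df.groupby(["segment_id", df.get("labeler", pd.Series(["?"] * len(df)))]):
        strikes: dict = {}
        for _, row in grp.iterrows():
            w = int(row["walker"]) - 1
            side = str(row["side"]).strip().lower()
            if side not in ("left", "right"):
                raise ValueError(f"side must be left/right, got {side!r}")
            strikes.setdefault(w, {"left": [], "right": []})[side].append(float(row["time_s"]))
        for w in strikes:
            strikes[w]["left"].sort()
            strikes[w]["right"].sort()
        out.append(FootStrikeLabels(strikes=strikes, segment_id=str(seg), labeler=str(labeler)))
    return out
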