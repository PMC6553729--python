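"""From tracked ankle/neck coordinates to relative walking phase and cadence.

The signal chain per walker:

1. **Detrend** — per frame, reference each ankle ordinate to the neck and
   normalize by skeleton height: (y_ankle − y_neck) / l.  This cancels
   camera translation exactly and camera zoom through the division.
2. **Clean** — linearly interpolate missing samples (ends held), replace
   samples ≥ 2 SD from the mean by interpolation, then z-normalize.
3. **Displacement** — left minus right ankle; one displacement cycle is two
   steps.
4. **Low-pass** — 3rd-order Butterworth, 2 Hz cutoff, applied
   forward-backward so the phase of the signal is untouched.
5. **Hilbert phase** — instantaneous phase of the analytic signal, the
   proxy for walking angle.

Relative phase is walker2 − walker1 wrapped to (−π, π]; the first and last
0.25 s are discarded before circular statistics to avoid analytic-signal
edge effects.  Cadence (steps/s) is twice the dominant frequency of the
displacement signal.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from . import circular_stats as cs
from .skeleton import LEFT_ANKLE, NECK, RIGHT_ANKLE
from .tracking import TrackedSegment


class SegmentRejected(RuntimeError):
    """A processing stage could not produce a usable signal."""

    def __init__(self, stage: str, reason: str):
        super().__init__(f"[{stage}] {reason}")
        self.stage = stage
        self.reason = reason


@dataclass
class AnkleSeries:
    """Detrended (neck-referenced, height-normalized) ankle ordinates."""

    t: np.ndarray  # seconds
    y_left: np.ndarray  # dimensionless, NaN where unobserved
    y_right: np.ndarray
    fps: float


@dataclass
class CadenceEstimate:
    steps_per_s: float
    confident: bool
    flatness: float  # spectral flatness of the displacement spectrum
    resolution: float  # frequency-bin spacing in cycles/s


@dataclass
class PhaseResult:
    rel_phase: np.ndarray  # per-sample, radians in (−π, π] (edges trimmed)
    t: np.ndarray  # seconds, aligned with rel_phase
    mean_rel_phase: float
    rel_phase_variance: float  # 1 − mean resultant length, in [0, 1]
    cadence1: CadenceEstimate
    cadence2: CadenceEstimate
    duration_s: float
    segment_id: str = ""
    quality: dict = field(default_factory=dict)


def detrend_ankle(tracked: TrackedSegment) -> tuple[AnkleSeries, AnkleSeries]:
    """Neck-referenced, height-normalized ankle ordinates per walker.

    The normalizing length l is the vertical span from the topmost detected
    keypoint to the *mean* ankle level.  Averaging the two ankles makes l
    insensitive to the gait cycle itself (the lower ankle bobs at twice the
    cycle frequency, so a raw min-to-max extent would inject harmonics into
    the normalized signal) while still cancelling camera zoom exactly.
    Invariant to adding a common offset to all keypoints of a frame and to
    uniform rescaling of the frame.  Frames where the neck, an ankle or a
    positive length is unavailable become NaN (interpolated later).
    """
    out = []
    n = tracked.n_frames
    t = np.arange(n) / tracked.fps
    for w in range(2):
        y = tracked.xy[w, :, :, 1]  # (n, 18)
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN gap frames
            top = np.nanmin(y, axis=1)  # y-down: min y = highest point
        mean_ankle = (y[:, LEFT_ANKLE] + y[:, RIGHT_ANKLE]) / 2.0
        l = mean_ankle - top
        l = np.where(np.isfinite(l) & (l > 0), l, np.nan)
        y_left = (y[:, LEFT_ANKLE] - y[:, NECK]) / l
        y_right = (y[:, RIGHT_ANKLE] - y[:, NECK]) / l
        out.append(AnkleSeries(t=t, y_left=y_left, y_right=y_right, fps=tracked.fps))
    return out[0], out[1]


def clean_series(x: np.ndarray, outlier_k: float = 2.0) -> tuple[np.ndarray, dict]:
    """Interpolate missing values, replace outliers, z-normalize.

    Missing (NaN) samples are linearly interpolated with ends held at the
    nearest observed value.  Samples at least ``outlier_k`` standard
    deviations from the mean (moments computed once on the filled series)
    are replaced by interpolation between their non-outlier neighbours.
    The result is normalized to mean 0, SD 1.
    """
    x = np.asarray(x, dtype=float).copy()
    n = x.size
    obs = np.isfinite(x)
    if obs.sum() < 2:
        raise SegmentRejected("clean", "fewer than 2 observed samples")
    idx = np.arange(n)
    filled = x.copy()
    filled[~obs] = np.interp(idx[~obs], idx[obs], x[obs])

    mu, sd = filled.mean(), filled.std()
    if sd <= 0:
        raise SegmentRejected("clean", "constant series — normalization undefined")
    outlier = np.abs(filled - mu) >= outlier_k * sd
    keep = ~outlier
    if keep.sum() < 2:
        raise SegmentRejected("clean", "outlier rule removed nearly all samples")
    replaced = filled.copy()
    replaced[outlier] = np.interp(idx[outlier], idx[keep], filled[keep])

    m2, s2 = replaced.mean(), replaced.std()
    if s2 <= 0:
        raise SegmentRejected("clean", "constant series after outlier replacement")
    z = (replaced - m2) / s2
    return z, {"interpolated": ~obs, "outlier_replaced": outlier}


def lowpass(x: np.ndarray, fs: float, cutoff: float = 2.0, order: int = 3, zero_phase: bool = True) -> np.ndarray:
    """Butterworth low-pass; forward-backward by default (zero phase, DC gain 1)."""
    if fs <= 2 * cutoff:
        raise ValueError(
            f"sampling rate {fs} Hz must exceed twice the {cutoff} Hz cutoff; resample the signal first"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x) if zero_phase else sps.sosfilt(sos, x)


def ankle_displacement(y_left: np.ndarray, y_right: np.ndarray) -> np.ndarray:
    """Left minus right ankle ordinate; one cycle = two steps."""
    return np.asarray(y_left) - np.asarray(y_right)


def hilbert_phase(d: np.ndarray) -> np.ndarray:
    """Instantaneous phase of the analytic signal, in (−π, π]."""
    d = np.asarray(d, dtype=float)
    if not np.any(np.abs(d) > 0):
        raise SegmentRejected("hilbert", "all-zero displacement — phase undefined")
    return np.angle(sps.hilbert(d))


def _dominant_sinusoid(d: np.ndarray, fs: float, resolution: float = 0.01):
    """Fit d ≈ a·sin(2πft) + b·cos(2πft) + c by FFT peak + Gauss-Newton.

    Used to condition the signal for the analytic transform: c is the
    baseline of the oscillation (nonzero whenever the series spans a
    non-integer number of cycles) and (a, b, f) provide a smooth periodic
    continuation for padding.
    """
    n = d.size
    t = np.arange(n) / fs
    base = int(round(fs / resolution))
    nfft = base * max(1, int(np.ceil(n / base)))
    spec = np.abs(np.fft.rfft(d * np.hanning(n), nfft))
    k = float(np.argmax(spec[1:]) + 1)
    ki = int(k)
    if 1 <= ki < spec.size - 1 and np.all(spec[ki - 1 : ki + 2] > 0):
        la, lb, lc = np.log(spec[ki - 1 : ki + 2])
        denom = la - 2 * lb + lc
        if denom < 0:
            k = ki + 0.5 * (la - lc) / denom
    f = k * fs / nfft
    a = b = c = 0.0
    for _ in range(10):
        w = 2 * np.pi * f
        S, C = np.sin(w * t), np.cos(w * t)
        J = np.column_stack([S, C, np.ones(n), 2 * np.pi * t * (a * C - b * S)])
        r = d - (a * S + b * C + c)
        step, *_ = np.linalg.lstsq(J, r, rcond=None)
        a += step[0]
        b += step[1]
        c += step[2]
        f = max(f + step[3], 1e-9)
        if np.max(np.abs(step)) < 1e-13:
            break
    return a, b, c, f


def _conditioned_phase(d: np.ndarray, fs: float, cutoff: float = 2.0, pad_cycles: float = 3.0,
                       zero_phase: bool = True):
    """Low-pass + Hilbert phase with sinusoid-continuation padding.

    The finite analytic transform leaks badly when the window covers a
    non-integer number of gait cycles; extending the displacement with a
    tapered continuation of its fitted dominant sinusoid (baseline removed)
    pushes both the filter transients and the Hilbert edge error into the
    discarded padding.  Returns (phase, filtered displacement) over the
    original samples.
    """
    n = d.size
    a, b, c, f = _dominant_sinusoid(d, fs)
    d0 = d - c
    P = int(round(pad_cycles * fs / f)) if f > 0 else 0
    if P > 0:
        t_left = np.arange(-P, 0) / fs
        t_right = np.arange(n, n + P) / fs
        model = lambda tt: a * np.sin(2 * np.pi * f * tt) + b * np.cos(2 * np.pi * f * tt)
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(1, P + 1) / P))  # 0 -> 1
        ext = np.concatenate([model(t_left) * ramp, d0, model(t_right) * ramp[::-1]])
    else:
        ext = d0
    filt = lowpass(ext, fs, cutoff=cutoff, zero_phase=zero_phase)
    phase = hilbert_phase(filt)
    return phase[P : P + n], filt[P : P + n]


def relative_phase(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """wrap(p1 − p2) into (−π, π]."""
    p1, p2 = np.asarray(p1), np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("phase series must have equal length")
    return cs.wrap_angle(p1 - p2)


def walking_frequency(
    d: np.ndarray,
    fs: float,
    resolution: float = 0.01,
    flatness_threshold: float = 0.1,
    min_cycles: float = 2.0,
) -> CadenceEstimate:
    """Cadence in steps/s: twice the peak frequency of the displacement FFT.

    The spectrum is Hann-windowed and zero-padded so bins land on multiples
    of ``resolution`` (cycles/s); DC is excluded from the peak search.  The
    estimate is flagged low-confidence when the power spectrum is too flat
    (no dominant peak, e.g. pure noise) or the segment spans fewer than
    ``min_cycles`` displacement cycles at the detected frequency.
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    if n < 4:
        raise ValueError("series too short for a spectrum")
    base = int(round(fs / resolution))
    nfft = base * max(1, int(np.ceil(n / base)))
    spec = np.abs(np.fft.rfft(d * np.hanning(n), nfft))
    df = fs / nfft
    power = spec[1:] ** 2  # DC excluded
    peak = int(np.argmax(power)) + 1
    f_cycles = peak * df

    p = power / power.sum()
    flatness = float(np.exp(np.mean(np.log(p + 1e-300))) / np.mean(p + 1e-300))
    enough_cycles = (n / fs) * f_cycles >= min_cycles
    return CadenceEstimate(
        steps_per_s=2.0 * f_cycles,
        confident=bool(flatness < flatness_threshold and enough_cycles),
        flatness=flatness,
        resolution=df,
    )


def analyze_segment(
    tracked: TrackedSegment,
    edge_margin_s: float = 0.25,
    min_duration_s: float = 2.0,
    cutoff_hz: float = 2.0,
    outlier_k: float = 2.0,
    segment_id: str = "",
) -> PhaseResult:
    """Run the full chain on a tracked pair and summarize it.

    Relative phase is walker2 − walker1.  ``edge_margin_s`` is discarded
    from both ends of the phase series before circular statistics.
    """
    n = tracked.n_frames
    fps = tracked.fps
    duration = (n - 1) / fps
    if duration < min_duration_s:
        raise SegmentRejected("duration", f"segment spans {duration:.2f} s < {min_duration_s} s")

    a1, a2 = detrend_ankle(tracked)
    cleaned = []
    n_interp = 0
    n_outlier = 0
    for series in (a1, a2):
        yl, info_l = clean_series(series.y_left, outlier_k)
        yr, info_r = clean_series(series.y_right, outlier_k)
        n_interp += int(info_l["interpolated"].sum() + info_r["interpolated"].sum())
        n_outlier += int(info_l["outlier_replaced"].sum() + info_r["outlier_replaced"].sum())
        cleaned.append((yl, yr))

    displacements = []
    phases = []
    for yl, yr in cleaned:
        phase, d = _conditioned_phase(ankle_displacement(yl, yr), fps, cutoff=cutoff_hz)
        displacements.append(d)
        phases.append(phase)

    rel = relative_phase(phases[1], phases[0])  # walker2 − walker1
    margin = int(round(edge_margin_s * fps))
    if n - 2 * margin < 2:
        raise SegmentRejected("phase", "segment too short after edge trimming")
    core = rel[margin : n - margin] if margin > 0 else rel
    t_core = a1.t[margin : n - margin] if margin > 0 else a1.t

    mean_phase = cs.circular_mean(core)
    variance = cs.circular_variance(core)
    cad1 = walking_frequency(displacements[0], fps)
    cad2 = walking_frequency(displacements[1], fps)

    total = 4 * n
    quality = {
        "frac_interpolated": n_interp / total,
        "frac_outlier_replaced": n_outlier / total,
        **tracked.quality,
    }
    return PhaseResult(
        rel_phase=core,
        t=t_core,
        mean_rel_phase=mean_phase,
        rel_phase_variance=variance,
        cadence1=cad1,
        cadence2=cad2,
        duration_s=duration,
        segment_id=segment_id or tracked.provenance,
        quality=quality,
    )


def analyze_frames(frames, fps: float, mode: str = "joint", **kwargs):
    """Convenience end-to-end run on raw frames: seed the pair from the
    first frame, track it, analyze it.  Returns (PhaseResult, TrackedSegment).
    """
    from .pair_detection import check_pair
    from .tracking import track_pair

    first = frames[0]
    seed = None
    import itertools

    for a, b in itertools.combinations(first.skeletons, 2):
        decision = check_pair(a, b)
        if decision.accepted:
            seed = decision
            break
    if seed is None:
        raise SegmentRejected("detection", "no accepted pair in the first frame")
    tracked = track_pair(frames, seed, fps=fps, mode=mode)
    return analyze_segment(tracked, **kwargs), tracked
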