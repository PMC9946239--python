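"""Behavioral measurement procedures for (simulated or tracked) trajectories.

Implements the selection and measurement pipeline applied to 50 Hz video
tracks of freely swimming cells, and equally applicable to simulated
trajectories: orientation flip correction, trajectory selection filters,
backward-swimming (avoiding-reaction) detection via the sign of
``m . o`` (motion vector dotted with the anterior-pointing orientation
vector), total reorientation angles, and sinusoidal fits of the in-plane
orientation during helicoidal swimming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["TrackedTrajectory", "flip_correction", "is_immobile",
           "turning_balance", "select_trajectories",
           "detect_avoiding_reactions", "AvoidingReaction",
           "reorientation_angle", "reorientation_before_after",
           "helicoid_fit", "HelicoidFit", "reaction_statistics"]


@dataclass
class TrackedTrajectory:
    """Planar track: time (s), position (um) and in-plane orientation (deg).

    ``eccentricity`` (ellipse fit, in [0, 1]) is optional and only consumed
    when present; simulated trajectories take orientation from the pose.
    """
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    gamma: np.ndarray
    eccentricity: Optional[np.ndarray] = None

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.gamma = np.asarray(self.gamma, float)
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("time must be strictly increasing")
        for arr in (self.x, self.y, self.gamma):
            if len(arr) != len(self.t):
                raise ValueError("all series must share the time grid")
            if not np.all(np.isfinite(arr)):
                raise ValueError("coordinates must be finite")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @classmethod
    def from_simulation(cls, traj) -> "TrackedTrajectory":
        """Adapt a :class:`paramecium.kinematics.Trajectory`."""
        return cls(t=traj.t, x=traj.x[:, 0], y=traj.x[:, 1],
                   gamma=traj.gamma)


def _wrap_deg(a):
    """Wrap angle differences into (-180, 180]."""
    return (np.asarray(a, float) + 180.0) % 360.0 - 180.0


def flip_correction(traj: TrackedTrajectory,
                    threshold: float = 20.0) -> TrackedTrajectory:
    """Correct front/rear identification errors in the orientation.

    Whenever the orientation turns by more than ``threshold`` degrees
    between two successive frames, the remaining angles are flipped by
    180 degrees (tracking software occasionally swaps the cell's ends).
    """
    gamma = np.array(traj.gamma, float, copy=True)
    flip = 0.0
    out = np.empty_like(gamma)
    out[0] = gamma[0]
    for i in range(1, len(gamma)):
        cand = gamma[i] + flip
        if abs(_wrap_deg(cand - out[i - 1])) > threshold:
            flip += 180.0
            cand = gamma[i] + flip
        out[i] = cand
    out = _wrap_deg(out)
    return TrackedTrajectory(t=traj.t, x=traj.x, y=traj.y, gamma=out,
                             eccentricity=traj.eccentricity)


def is_immobile(traj: TrackedTrajectory, speed_min: float = 20.0,
                window: float = 0.5) -> bool:
    """Median speed below ``speed_min`` um/s over every ``window``-s span."""
    dt = np.diff(traj.t)
    speed = np.hypot(np.diff(traj.x), np.diff(traj.y)) / dt
    n_win = max(1, int(round(window / np.median(dt))))
    if len(speed) < n_win:
        return float(np.median(speed)) < speed_min
    med = np.array([np.median(speed[i:i + n_win])
                    for i in range(0, len(speed) - n_win + 1)])
    return bool(np.median(med) < speed_min)


def turning_balance(traj: TrackedTrajectory) -> float:
    """Proportion of frames turning clockwise (0.5 for helicoids)."""
    d = _wrap_deg(np.diff(traj.gamma))
    turning = d[np.abs(d) > 1e-9]
    if len(turning) == 0:
        return 0.5
    return float(np.mean(turning < 0.0))


def select_trajectories(trajs: Sequence[TrackedTrajectory],
                        min_duration: float = 1.0,
                        circling_threshold: float = 0.1,
                        circling_min_duration: float = 4.0,
                        speed_min: float = 20.0) -> List[TrackedTrajectory]:
    """Apply the trajectory selection filters.

    Discards tracks shorter than 1 s, immobile tracks, and (for tracks
    longer than 4 s) circling tracks whose clockwise/anticlockwise turning
    proportions differ from 0.5 by more than 0.1.
    """
    kept = []
    for tr in trajs:
        if tr.duration < min_duration:
            continue
        if is_immobile(tr, speed_min=speed_min):
            continue
        if tr.duration > circling_min_duration:
            if abs(turning_balance(tr) - 0.5) > circling_threshold:
                continue
        kept.append(tr)
    return kept


@dataclass
class AvoidingReaction:
    """One backward-swimming episode."""
    start_index: int
    end_index: int                 # inclusive index of last backward frame
    start_s: float
    duration_ms: float


def detect_avoiding_reactions(traj: TrackedTrajectory) \
        -> List[AvoidingReaction]:
    """Backward-swimming segments: motion vector opposite the orientation.

    The instantaneous motion vector m is computed by central differences;
    backward swimming is ``m . o < 0`` with o the anterior-pointing unit
    vector.  Episodes spanning only a single pair of frames are discarded.
    """
    t, x, y = traj.t, traj.x, traj.y
    if len(t) < 3:
        return []
    mx = np.gradient(x, t)
    my = np.gradient(y, t)
    g = np.deg2rad(traj.gamma)
    dot = mx * np.cos(g) + my * np.sin(g)
    back = dot < 0.0
    reactions = []
    i = 0
    n = len(back)
    while i < n:
        if back[i]:
            j = i
            while j + 1 < n and back[j + 1]:
                j += 1
            # single pair of frames = backward over exactly 2 frames
            if j - i + 1 > 2:
                reactions.append(AvoidingReaction(
                    start_index=i, end_index=j, start_s=float(t[i]),
                    duration_ms=float((t[j] - t[i]) * 1e3)))
            i = j + 1
        else:
            i += 1
    return reactions


def reorientation_angle(traj: TrackedTrajectory, reaction: AvoidingReaction,
                        eccentricity_min: float = 0.8) -> Optional[float]:
    """Total reorientation (deg) over a reaction; None if non-planar.

    Sums the successive instantaneous orientation changes across the
    reaction.  When an eccentricity series is present and dips below
    ``eccentricity_min`` during the reaction, the event is excluded
    (the turn left the focal plane).
    """
    i, j = reaction.start_index, reaction.end_index
    if traj.eccentricity is not None:
        if np.min(traj.eccentricity[i:j + 1]) < eccentricity_min:
            return None
    steps = _wrap_deg(np.diff(traj.gamma[i:j + 1]))
    return float(np.sum(steps))


def reorientation_before_after(traj: TrackedTrajectory, t_stim: float,
                               window: float = 1.0) -> float:
    """Change in mean orientation over ``window`` s before vs after t_stim.

    The averaging window matches the spinning period, so the helicoidal
    oscillation averages out; used for simulated pulse responses.
    """
    g = np.deg2rad(traj.gamma)
    ux, uy = np.cos(g), np.sin(g)
    before = (traj.t >= t_stim - window) & (traj.t < t_stim)
    after = (traj.t > t_stim) & (traj.t <= t_stim + window)
    if before.sum() == 0 or after.sum() == 0:
        raise ValueError("stimulus window outside the trajectory")
    a0 = math.atan2(uy[before].mean(), ux[before].mean())
    a1 = math.atan2(uy[after].mean(), ux[after].mean())
    return float(_wrap_deg(math.degrees(a1 - a0)))


@dataclass
class HelicoidFit:
    period: float        # s
    amplitude: float     # deg
    mean: float          # deg
    r_squared: float
    ok: bool             # False when the sinusoid explains little variance


def helicoid_fit(traj: TrackedTrajectory, r2_min: float = 0.5) -> HelicoidFit:
    """Least-squares sinusoid fit of the orientation angle gamma(t).

    Requires at least two full periods of data.  The period is seeded from
    the dominant Fourier component and refined by nonlinear least squares
    of ``gamma = mean + A sin(2 pi t / T + phi)``.
    """
    t = traj.t - traj.t[0]
    g = np.rad2deg(np.unwrap(np.deg2rad(traj.gamma)))

    # seed the period from the dominant Fourier component of the
    # (roughly) detrended signal
    rough = g - np.polynomial.polynomial.polyval(
        t, np.polynomial.polynomial.polyfit(t, g, 1))
    dt = float(np.median(np.diff(t)))
    freqs = np.fft.rfftfreq(len(t), dt)
    spectrum = np.abs(np.fft.rfft(rough - rough.mean()))
    spectrum[0] = 0.0
    f0 = freqs[int(np.argmax(spectrum))]
    if f0 <= 0 or t[-1] * f0 < 2.0:
        return HelicoidFit(period=np.inf, amplitude=0.0,
                           mean=float(np.mean(g)), r_squared=0.0, ok=False)

    # joint fit: sinusoid plus a slow linear drift of the helicoid axis
    def model(tt, A, T, phi, c, b):
        return c + b * tt + A * np.sin(2.0 * math.pi * tt / T + phi)

    A0 = math.sqrt(2.0) * float(np.std(rough))
    try:
        popt, _ = curve_fit(model, t, g,
                            p0=[A0, 1.0 / f0, 0.0, float(np.mean(g)), 0.0],
                            maxfev=20000)
    except RuntimeError:
        return HelicoidFit(period=1.0 / f0, amplitude=A0,
                           mean=float(np.mean(g)), r_squared=0.0, ok=False)
    A, T, phi, c, b = popt
    pred = model(t, *popt)
    line = c + b * t
    ss_res = float(np.sum((g - pred) ** 2))
    ss_tot = float(np.sum((g - line) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return HelicoidFit(period=abs(float(T)), amplitude=abs(float(A)),
                       mean=float(c), r_squared=r2,
                       ok=r2 >= r2_min)


def reaction_statistics(trajs: Sequence[TrackedTrajectory]) -> dict:
    """Population summary: reaction rate, durations, angles, correlation."""
    durations, angles = [], []
    total_time = 0.0
    count = 0
    for tr in trajs:
        total_time += tr.duration
        for r in detect_avoiding_reactions(tr):
            count += 1
            ang = reorientation_angle(tr, r)
            if ang is not None:
                durations.append(r.duration_ms)
                angles.append(abs(ang))
    out = {
        "n_reactions": count,
        "rate_hz": count / total_time if total_time > 0 else float("nan"),
        "mean_duration_ms": float(np.mean(durations)) if durations else float("nan"),
        "mean_angle_deg": float(np.mean(angles)) if angles else float("nan"),
    }
    if len(durations) >= 3:
        r = np.corrcoef(durations, angles)[0, 1]
        out["duration_angle_correlation"] = float(r)
    return out
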