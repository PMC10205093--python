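"""Synthetic W-track alternation behavior.

Generates the behavioral covariates that hippocampal encoding models condition
on: linearized position ``x(t)`` (cm, 0-300), running speed ``s(t)`` (cm/s),
movement direction ``d(t)`` (1 = inbound toward the center arm, 0 = outbound),
and instantaneous theta phase ``phi(t)`` (radians, wrapped to [-pi, pi)), all
sampled on a uniform grid (10 ms by default).

The linearized coordinate follows the convention of distance from the tip of
the center arm: [0, 80] center arm, (80, 190] right arm, (190, 300] left arm.
The left arm is its own coordinate segment (190 + distance from the junction),
so x jumps from 80 to 190 when the animal enters the left arm; speed is always
computed from physical arc-length displacement and is continuous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "Trajectory",
    "simulate_trajectory",
    "theta_phase_series",
    "arm_of",
    "smooth_speed",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

TRACK_LENGTH_CM = 300.0
CENTER_END_CM = 80.0
RIGHT_END_CM = 190.0
#: run/rest speed threshold used throughout (cm/s)
SPEED_THRESHOLD_CMPS = 2.0
#: moving-average window used to smooth speed (s)
SPEED_SMOOTH_S = 0.25


@dataclass
class Trajectory:
    """Time-aligned behavioral covariates on a uniform time grid.

    Attributes
    ----------
    dt_s : float
        Seconds per bin.
    x : ndarray
        Linearized position, cm, in [0, 300].
    s : ndarray
        Speed, cm/s, nonnegative.
    d : ndarray
        Direction indicator, 1 inbound (toward center arm), 0 outbound.
    phi : ndarray
        Theta phase, radians, in [-pi, pi).
    """

    dt_s: float
    x: np.ndarray
    s: np.ndarray
    d: np.ndarray
    phi: np.ndarray
    #: bins where x jumps between coordinate segments (junction crossings)
    segment_jumps: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.d = np.asarray(self.d, dtype=int)
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.x)
        if n < 1:
            raise ValueError("Trajectory must contain at least one bin")
        if not (len(self.s) == len(self.d) == len(self.phi) == n):
            raise ValueError("all covariate series must share the same length")
        if self.x.min() < 0 or self.x.max() > TRACK_LENGTH_CM:
            raise ValueError("position out of [0, 300] cm range")
        if self.s.min() < 0:
            raise ValueError("speed must be nonnegative")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def T(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return self.T * self.dt_s

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.T)


def arm_of(x: float) -> str:
    """Map a linearized position to its W-track arm label.

    Boundary positions (exactly 80 or 190 cm) go to the inner-listed arm
    (center and right respectively), making the assignment deterministic.
    """
    if not 0 <= x <= TRACK_LENGTH_CM:
        raise ValueError(f"position {x} cm outside the track [0, 300]")
    if x <= CENTER_END_CM:
        return "center"
    if x <= RIGHT_END_CM:
        return "right"
    return "left"


def theta_phase_series(
    T: int,
    dt_s: float = 0.01,
    freq_hz: float = 8.0,
    freq_jitter_hz: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Instantaneous theta phase with slowly drifting frequency.

    The instantaneous frequency follows an Ornstein-Uhlenbeck-style drift
    around ``freq_hz`` with stationary standard deviation ``freq_jitter_hz``
    (time constant 1 s); phase advances by ``2*pi*f[t]*dt_s`` per bin and is
    wrapped to [-pi, pi).  ``freq_jitter_hz = 0`` gives an exact constant
    phase increment.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    rng = np.random.default_rng(seed)
    if freq_jitter_hz > 0:
        tau = 1.0  # s, drift time constant
        rho = np.exp(-dt_s / tau)
        innov_sd = freq_jitter_hz * np.sqrt(1.0 - rho**2)
        z = np.empty(T)
        z[0] = rng.normal(0.0, freq_jitter_hz)
        z[1:] = rng.normal(0.0, innov_sd, size=T - 1)
        dev = lfilter([1.0], [1.0, -rho], z)
        freq = freq_hz + dev
    else:
        freq = np.full(T, freq_hz)
    phase = -np.pi + 2.0 * np.pi * dt_s * np.concatenate(([0.0], np.cumsum(freq[:-1])))
    return wrap_phase(phase)


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to [-pi, pi)."""
    return np.mod(np.asarray(phi) + np.pi, 2.0 * np.pi) - np.pi


def smooth_speed(raw_cmps: np.ndarray, dt_s: float) -> np.ndarray:
    """Centered moving-average speed smoothing (0.25 s window, edge padded)."""
    w = max(int(round(SPEED_SMOOTH_S / dt_s)), 1)
    if w == 1 or len(raw_cmps) < 2:
        return np.asarray(raw_cmps, dtype=float)
    padded = np.pad(raw_cmps, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(padded, np.ones(w) / w, mode="valid")


def _run_bout_speeds(distance_cm: float, peak_cmps: float, dt_s: float) -> np.ndarray:
    """Per-bin speeds of a single run covering `distance_cm` with a sinusoidal
    speed profile peaking at `peak_cmps`."""
    dur = np.pi * distance_cm / (2.0 * peak_cmps)
    n = max(int(round(dur / dt_s)), 2)
    tt = (np.arange(n) + 0.5) / n
    sp = peak_cmps * np.sin(np.pi * tt)
    # rescale so displacement integrates exactly to distance_cm
    sp *= distance_cm / (sp.sum() * dt_s)
    return sp


def simulate_trajectory(
    duration_s: float,
    dt_s: float = 0.01,
    speed_mean: float = 20.0,
    speed_sd: float = 5.0,
    seed: int = 0,
    rest_mean_s: float = 2.0,
    theta_freq_hz: float = 8.0,
    theta_jitter_hz: float = 1.0,
) -> Trajectory:
    """Simulate W-track alternation behavior.

    The animal alternates full journeys center -> right -> center -> left ->
    center.  Each one-way run has a sinusoidal speed profile with peak speed
    drawn from a truncated normal (``speed_mean``, ``speed_sd``, floor 5 cm/s)
    and rests at arm ends for an exponential dwell (mean ``rest_mean_s``).
    Direction flips only at arm-end turnarounds: d = 0 on the way out (and
    while resting at the outer arm), 1 on the way back in.

    Identical arguments and seed give bit-identical output.
    """
    if duration_s <= 0 or dt_s <= 0:
        raise ValueError("duration_s and dt_s must be positive")
    if speed_mean <= SPEED_THRESHOLD_CMPS:
        raise ValueError("speed_mean must exceed the 2 cm/s run threshold")
    rng = np.random.default_rng(seed)
    T = int(round(duration_s / dt_s))
    if T < 1:
        raise ValueError("duration shorter than one bin")

    arc_dist = RIGHT_END_CM  # center tip -> either outer arm end, cm
    pos_segments: list[np.ndarray] = []  # arc-length position p in [0, 190]
    dir_segments: list[np.ndarray] = []
    arm_segments: list[np.ndarray] = []  # 0 = right journey, 1 = left journey
    total = 0
    journey = 0  # alternation counter: even -> right, odd -> left
    while total < T:
        which = journey % 2
        for inbound in (0, 1):
            peak = max(rng.normal(speed_mean, speed_sd), 5.0)
            sp = _run_bout_speeds(arc_dist, peak, dt_s)
            disp = np.cumsum(sp) * dt_s
            p = disp if inbound == 0 else arc_dist - disp
            p = np.clip(p, 0.0, arc_dist)
            pos_segments.append(p)
            dir_segments.append(np.full(len(p), inbound, dtype=int))
            arm_segments.append(np.full(len(p), which, dtype=int))
            total += len(p)
            # dwell at the turn-around point (arm end or center tip)
            n_rest = int(round(rng.exponential(rest_mean_s) / dt_s))
            if n_rest > 0:
                rest_p = np.full(n_rest, p[-1])
                pos_segments.append(rest_p)
                # keep the direction of the run just completed until turnaround
                dir_segments.append(np.full(n_rest, inbound, dtype=int))
                arm_segments.append(np.full(n_rest, which, dtype=int))
                total += n_rest
        journey += 1

    p = np.concatenate(pos_segments)[:T]
    d = np.concatenate(dir_segments)[:T]
    arm = np.concatenate(arm_segments)[:T]

    # physical speed from arc-length displacement, smoothed (0.25 s window)
    raw = np.abs(np.diff(p, prepend=p[0])) / dt_s
    s = smooth_speed(raw, dt_s)

    # map arc length to the printed linearized coordinate: left-arm positions
    # beyond the junction are offset into (190, 300]
    x = p.copy()
    on_left_arm = (arm == 1) & (p > CENTER_END_CM)
    x[on_left_arm] = (RIGHT_END_CM - CENTER_END_CM) + p[on_left_arm]
    jumps = np.flatnonzero(np.abs(np.diff(x)) > 3.0 * max(speed_mean + 4 * speed_sd, 10.0) * dt_s) + 1

    phi = theta_phase_series(
        T, dt_s, freq_hz=theta_freq_hz, freq_jitter_hz=theta_jitter_hz,
        seed=int(rng.integers(2**31)),
    )
    return Trajectory(dt_s=dt_s, x=x, s=s, d=d, phi=phi, segment_jumps=jumps)


_TRAJ_COLUMNS = ["t_index", "x_cm", "s_cmps", "d_flag", "phi_rad"]


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Write a trajectory as plain delimited text, one row per bin."""
    df = pd.DataFrame(
        {
            "t_index": traj.t,
            "x_cm": traj.x,
            "s_cmps": traj.s,
            "d_flag": traj.d,
            "phi_rad": traj.phi,
        }
    )
    df.to_csv(path, index=False)


def read_trajectory_csv(path, dt_s: float = 0.01) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file missing columns: {missing}")
    if df[_TRAJ_COLUMNS].isna().any().any():
        raise ValueError("trajectory file contains missing values")
    return Trajectory(
        dt_s=dt_s,
        x=df["x_cm"].to_numpy(float),
        s=df["s_cmps"].to_numpy(float),
        d=df["d_flag"].to_numpy(int),
        phi=df["phi_rad"].to_numpy(float),
    )
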