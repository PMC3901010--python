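"""Movement data for the simulated animal.

A :class:`Trajectory` is the sole behavioural input to the model: a uniformly
sampled series of positions in a square arena, together with the per-step
displacements, running speed and heading direction derived from them.  Three
sources are supported:

* a momentum-driven random walk with wall avoidance (open-field foraging),
* a constant-velocity straight line (linear-track style transects),
* a recorded trajectory loaded from a delimited ``t,x,y`` table and
  up-sampled to the simulation time step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "WalkParams",
    "generate_random_walk",
    "generate_straight_line",
    "load_trajectory",
    "reflect_at_wall",
    "write_trajectory",
]


@dataclass
class Trajectory:
    """Uniformly sampled path of the simulated animal.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds, ``t[i] = t[0] + i * dt``.
    x, y : ndarray
        Position in cm.
    dx, dy : ndarray
        Per-step displacement in cm; ``dx[0] = dy[0] = 0``.
    speed : ndarray
        Running speed ``sqrt(dx**2 + dy**2) / dt`` in cm/s.
    heading : ndarray
        Heading direction ``atan2(dy, dx)`` in degrees, wrapped to
        ``[0, 360)``.  While stationary the previous heading is carried
        forward (the direction of travel is undefined at zero speed).
    dt : float
        Sample interval in seconds.
    arena_half_width : float or None
        Half-width of the square arena in cm, if bounded.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    speed: np.ndarray
    heading: np.ndarray
    dt: float
    arena_half_width: float | None = None

    @classmethod
    def from_positions(
        cls,
        t: np.ndarray,
        x: np.ndarray,
        y: np.ndarray,
        arena_half_width: float | None = None,
    ) -> "Trajectory":
        """Derive kinematics (steps, speed, heading) from a position series."""
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.size < 2:
            raise ValueError("trajectory needs at least two samples")
        steps = np.diff(t)
        dt = float(steps[0])
        if dt <= 0 or not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
            raise ValueError("time column must be uniform and strictly increasing")
        dx = np.concatenate([[0.0], np.diff(x)])
        dy = np.concatenate([[0.0], np.diff(y)])
        speed = np.hypot(dx, dy) / dt
        heading = _derive_heading(dx, dy)
        return cls(t, x, y, dx, dy, speed, heading, dt, arena_half_width)

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def mean_speed(self) -> float:
        """Mean running speed in cm/s (the initial zero-step sample excluded)."""
        return float(np.mean(self.speed[1:]))


def _derive_heading(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """atan2 heading in degrees [0, 360), holding the last value while still."""
    moving = (dx != 0.0) | (dy != 0.0)
    heading = np.degrees(np.arctan2(dy, dx)) % 360.0
    if not moving.all():
        idx = np.where(moving, np.arange(dx.size), -1)
        np.maximum.accumulate(idx, out=idx)
        first = np.argmax(moving) if moving.any() else 0
        heading = np.where(idx >= 0, heading[np.maximum(idx, 0)], heading[first])
    return heading


@dataclass
class WalkParams:
    """Parameters of the momentum random walk.

    ``step_size`` is the average step scale (cm per time step), ``momentum``
    the autoregressive weight on the previous step, ``reverse_factor`` the
    wall-avoidance reversal gain, applied to a step that would leave the
    arena.  Defaults generate open-field foraging at a mean running speed of
    roughly 23 cm/s in a 200 x 200 cm arena.
    """

    step_size: float = 1.7
    momentum: float = 0.999
    reverse_factor: float = 0.6
    arena_half_width: float = 100.0
    dt: float = 0.002
    initial_step: tuple[float, float] = (0.35, 0.35)
    seed: int | None = None

    def validate(self) -> None:
        values = [
            self.step_size,
            self.momentum,
            self.reverse_factor,
            self.arena_half_width,
            self.dt,
            *self.initial_step,
        ]
        if not all(math.isfinite(v) for v in values):
            raise ValueError("walk parameters must be finite")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.reverse_factor <= 0:
            raise ValueError("reverse_factor must be positive")
        if self.dt <= 0 or self.arena_half_width <= 0:
            raise ValueError("dt and arena_half_width must be positive")


def reflect_at_wall(step: float, reverse_factor: float) -> float:
    """Reverse a step that would carry the animal out of the arena.

    Applied per dimension, only to the offending component: the candidate
    step is replaced by ``-reverse_factor * step`` so the animal moves away
    from, rather than hugs, the wall.
    """
    return -reverse_factor * step


def generate_random_walk(
    params: WalkParams,
    duration: float,
    seed: int | None = None,
) -> Trajectory:
    """Momentum random walk inside a square arena, starting at the centre.

    Each step is ``step = s*(1-m)*p + m*step_prev`` per axis, with
    ``p ~ N(0, 1)`` drawn independently for x and y.  A step that would exit
    the arena is reversed by :func:`reflect_at_wall`; in the rare case that
    the reversed step still exits (e.g. deep in a corner), the position is
    clamped to the wall.  Reproducible for a fixed seed.
    """
    params.validate()
    if not (math.isfinite(duration) and duration > 0):
        raise ValueError("duration must be positive and finite")
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    n_steps = int(round(duration / params.dt))
    s = params.step_size
    m = params.momentum
    r = params.reverse_factor
    hw = params.arena_half_width
    gain = s * (1.0 - m)

    noise = rng.standard_normal((n_steps, 2))
    x = np.empty(n_steps + 1)
    y = np.empty(n_steps + 1)
    x[0] = 0.0
    y[0] = 0.0
    px, py = 0.0, 0.0
    sdx, sdy = params.initial_step

    for i in range(n_steps):
        sdx = gain * noise[i, 0] + m * sdx
        sdy = gain * noise[i, 1] + m * sdy
        nx = px + sdx
        if nx > hw or nx < -hw:
            sdx = -r * sdx
            nx = px + sdx
            if nx > hw or nx < -hw:
                nx = hw if nx > hw else -hw
                sdx = nx - px
        ny = py + sdy
        if ny > hw or ny < -hw:
            sdy = -r * sdy
            ny = py + sdy
            if ny > hw or ny < -hw:
                ny = hw if ny > hw else -hw
                sdy = ny - py
        px, py = nx, ny
        x[i + 1] = nx
        y[i + 1] = ny

    t = np.arange(n_steps + 1) * params.dt
    return Trajectory.from_positions(t, x, y, arena_half_width=hw)


def generate_straight_line(
    start: tuple[float, float],
    end: tuple[float, float],
    speed: float,
    dt: float = 0.002,
) -> Trajectory:
    """Constant-velocity path from ``start`` to ``end``.

    The classic linear-transect protocol: e.g. ``(-100, 0)`` to ``(100, 0)``
    at 5 cm/s crosses a 200 cm environment in 40 s with heading 0 throughout.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    x0, y0 = start
    x1, y1 = end
    length = math.hypot(x1 - x0, y1 - y0)
    if length == 0:
        raise ValueError("start and end coincide: zero-length path")
    n_steps = int(round(length / (speed * dt)))
    frac = np.arange(n_steps + 1) / n_steps
    t = np.arange(n_steps + 1) * dt
    x = x0 + frac * (x1 - x0)
    y = y0 + frac * (y1 - y0)
    return Trajectory.from_positions(t, x, y)


def load_trajectory(path, target_dt: float = 0.002) -> Trajectory:
    """Load a recorded ``t,x,y`` table (s, cm, cm) and up-sample.

    Recorded position data is typically sampled at 0.02 s; it is linearly
    interpolated down to the simulation step (``target_dt``, default
    0.002 s).  The target step must divide the source step.  Non-uniform or
    non-monotone time columns are rejected.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        t = df[cols["t"]].to_numpy(dtype=float)
        x = df[cols["x"]].to_numpy(dtype=float)
        y = df[cols["y"]].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"trajectory table must have columns t,x,y (missing {exc})")
    if t.size < 2:
        raise ValueError("trajectory table has fewer than two rows")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise ValueError("time column must be strictly increasing")
    src_dt = float(np.median(steps))
    if not np.allclose(steps, src_dt, rtol=1e-4, atol=1e-9):
        raise ValueError("time column must be uniformly sampled")
    ratio = src_dt / target_dt
    if abs(ratio - round(ratio)) > 1e-6 * max(1.0, ratio):
        raise ValueError(
            f"target_dt={target_dt} must divide the source step {src_dt}"
        )
    n_new = (t.size - 1) * int(round(ratio)) + 1
    t_new = t[0] + np.arange(n_new) * target_dt
    x_new = np.interp(t_new, t, x)
    y_new = np.interp(t_new, t, y)
    return Trajectory.from_positions(t_new - t_new[0], x_new, y_new)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as headered CSV ``t,x,y,speed,heading``."""
    pd.DataFrame(
        {
            "t": traj.t,
            "x": traj.x,
            "y": traj.y,
            "speed": traj.speed,
            "heading": traj.heading,
        }
    ).to_csv(path, index=False)
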