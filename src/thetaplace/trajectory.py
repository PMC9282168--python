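"""Random-foraging trajectory of a virtual rat in a square arena.

The rat's position follows

    dr/dt = v_t [cos(theta_t), sin(theta_t)],    theta_t = sigma_theta * w_t,

where ``w_t`` is a standard Wiener process, so heading increments are
Gaussian with standard deviation ``sigma_theta * sqrt(dt)``, and the speed
``v_t`` relaxes toward a long-term mean (0.30 m/s) through an
Ornstein-Uhlenbeck process.  Near a wall the heading is deflected parallel
to it; any step that would leave the arena is resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrajectoryParams",
    "Trajectory",
    "simulate_trajectory",
    "save_trajectory",
    "load_trajectory",
]


@dataclass(frozen=True)
class TrajectoryParams:
    """Parameters of the stochastic foraging process (SI units)."""

    sigma_theta: float = 1.0      # tortuosity, rad / sqrt(s)
    mean_speed: float = 0.30      # long-term mean speed, m/s
    dt: float = 0.01              # trajectory time step, s
    duration: float = 3600.0      # s
    arena_size: float = 1.0       # side of the square arena, m
    wall_margin: float = 0.02     # distance at which wall deflection kicks in, m
    speed_relax_time: float = 0.5  # OU relaxation time of the speed, s
    speed_noise: float = 0.08     # stationary s.d. of the OU speed, m/s
    seed: int | None = None
    start: tuple[float, float] | None = None   # default: arena centre
    start_heading: float | None = None         # rad; default: random
    max_resample: int = field(default=1000, repr=False)

    def validate(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        if self.sigma_theta < 0:
            raise ValueError("sigma_theta must be non-negative")
        if not 0 <= self.wall_margin < self.arena_size / 2:
            raise ValueError("wall_margin must lie in [0, arena_size/2)")
        if self.speed_relax_time <= 0:
            raise ValueError("speed_relax_time must be positive")


@dataclass
class Trajectory:
    """Time-stamped positions, headings and speeds of the virtual rat."""

    times: np.ndarray      # (N,), s
    positions: np.ndarray  # (N, 2), m
    headings: np.ndarray   # (N,), rad
    speeds: np.ndarray     # (N,), m/s
    arena_size: float = 1.0

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def _deflect_parallel(theta: float, x: float, y: float, margin: float,
                      size: float) -> float:
    """Wall rule: heading into a wall within ``margin`` is replaced by the
    parallel direction nearer the current heading; a perpendicular approach
    (tie) breaks toward the arena-centre side.  Applied per wall so that a
    corner approach resolves to the direction leaving both walls."""
    dx, dy = np.cos(theta), np.sin(theta)
    half = size / 2.0
    # x walls
    if (x < margin and dx < 0) or (x > size - margin and dx > 0):
        if dy > 0:
            theta = np.pi / 2
        elif dy < 0:
            theta = -np.pi / 2
        else:  # perpendicular: head toward centre in y
            theta = np.pi / 2 if y < half else -np.pi / 2
        dx, dy = 0.0, np.sin(theta)
    # y walls (heading possibly already deflected)
    if (y < margin and dy < 0) or (y > size - margin and dy > 0):
        if dx > 0:
            theta = 0.0
        elif dx < 0:
            theta = np.pi
        else:
            theta = 0.0 if x < half else np.pi
    return theta


def simulate_trajectory(params: TrajectoryParams) -> Trajectory:
    """Simulate the foraging trajectory.

    Returns ``duration/dt + 1`` samples.  Steps that would exit the arena
    redraw the Wiener (heading) increment only, up to ``max_resample``
    attempts, after which a degenerate-geometry error is raised.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration / params.dt)) + 1
    dt = params.dt
    size = params.arena_size

    times = np.arange(n) * dt
    pos = np.empty((n, 2))
    head = np.empty(n)
    speed = np.empty(n)

    pos[0] = (size / 2.0, size / 2.0) if params.start is None else params.start
    if not (0 <= pos[0, 0] <= size and 0 <= pos[0, 1] <= size):
        raise ValueError("start position outside the arena")
    head[0] = (rng.uniform(0, 2 * np.pi) if params.start_heading is None
               else params.start_heading)
    speed[0] = params.mean_speed

    # exact OU discretisation for the speed
    a = np.exp(-dt / params.speed_relax_time)
    ou_sd = params.speed_noise * np.sqrt(1.0 - a * a)
    sig_h = params.sigma_theta * np.sqrt(dt)

    for i in range(1, n):
        v = params.mean_speed + (speed[i - 1] - params.mean_speed) * a
        if ou_sd > 0:
            v += ou_sd * rng.standard_normal()
        v = max(v, 0.0)
        x, y = pos[i - 1]
        for attempt in range(params.max_resample):
            theta = head[i - 1]
            if sig_h > 0:
                theta = theta + sig_h * rng.standard_normal()
            theta = _deflect_parallel(theta, x, y, params.wall_margin, size)
            nx = x + v * dt * np.cos(theta)
            ny = y + v * dt * np.sin(theta)
            if 0.0 <= nx <= size and 0.0 <= ny <= size:
                break
        else:
            raise RuntimeError(
                "degenerate geometry: no valid step after "
                f"{params.max_resample} resamples at t={times[i]:.2f}s")
        pos[i] = (nx, ny)
        head[i] = np.arctan2(np.sin(theta), np.cos(theta))
        speed[i] = v

    return Trajectory(times, pos, head, speed, arena_size=size)


def save_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as delimited text with columns t,x,y,theta,speed."""
    data = np.column_stack([traj.times, traj.positions, traj.headings,
                            traj.speeds])
    header = f"t x y theta speed (arena_size={traj.arena_size})"
    np.savetxt(path, data, header=header)


def load_trajectory(path) -> Trajectory:
    with open(path) as fh:
        first = fh.readline()
    arena = 1.0
    if "arena_size=" in first:
        arena = float(first.split("arena_size=")[1].rstrip(")\n"))
    data = np.loadtxt(path)
    return Trajectory(data[:, 0], data[:, 1:3], data[:, 3], data[:, 4],
                      arena_size=arena)
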