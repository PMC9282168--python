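"""Receptive-field recovery and spatiotemporal analysis.

Rate maps are occupancy-averaged responses on a 40 x 40 lattice of the
arena.  Spatial fields are fitted with the truncated-Gaussian bump

    f_s(r) = alpha_c * exp(-ln5 ||r - r_c||^2 / R^2),

temporal traces with the phase-modulation model

    f(t) = alpha * exp(k_phi (cos(2 pi F t - phi) - 1)),

both by nonlinear least squares; the fitting error is the ratio of the
summed squared residual to the summed squared data.  A cell is a place
cell when the fitted centre lies inside the arena, the radius exceeds
5 cm and the fitting error is below 40%.  Phase precession is quantified
along a traversal by the Pearson correlation between fitted phases and
the normalised projected distance in the current running direction
(pdcd: field entry -> 0, exit -> 1 along the current chord).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from .ec import DegenerateChordError, ECPopulation
from .sparse import ModelState, SparseCodingModel, run_section
from .trajectory import Trajectory, TrajectoryParams, simulate_trajectory

__all__ = [
    "RateMap", "SpatialFit", "TemporalFit", "PrecessionSummary",
    "recover_rate_maps", "fit_spatial_field", "select_place_cells",
    "response_trace_at", "fit_temporal_response", "normalized_pdcd",
    "measure_precession",
]

_LN5 = np.log(5.0)


@dataclass
class RateMap:
    """Occupancy-averaged response of one cell on an n x n lattice."""

    grid: np.ndarray        # (n, n); grid[i, j] = mean rate in bin (x_i, y_j)
    occupancy: np.ndarray   # (n, n) visit counts; 0 marks unvisited bins
    bin_size: float         # m

    @property
    def visited(self) -> np.ndarray:
        return self.occupancy > 0

    def bin_centers(self) -> np.ndarray:
        n = self.grid.shape[0]
        return (np.arange(n) + 0.5) * self.bin_size


@dataclass
class SpatialFit:
    amplitude: float
    center: np.ndarray      # (2,), m
    radius: float           # m
    fit_error: float        # SSR / sum of squared map values
    converged: bool = True


@dataclass
class TemporalFit:
    amplitude: float
    k_phi: float
    freq: float             # Hz
    phase: float            # deg, in [0, 360)
    fit_error: float
    valid: bool = True      # False for flat/degenerate traces


@dataclass
class PrecessionSummary:
    pdcd_values: np.ndarray   # normalised pdcd per sampled position
    phases: np.ndarray        # fitted phase per position, deg
    entry_phase: float        # deg, first in-field sample
    exit_phase: float         # deg, last in-field sample
    correlation: float        # Pearson r of (pdcd, phase); nan if flagged
    wrapped: bool = False     # phase series crossed the 0/360 boundary


def run_inference(coder: SparseCodingModel, population: ECPopulation,
                  trajectory: Trajectory, chunk: int = 4000) -> np.ndarray:
    """Settled responses of every model cell along a trajectory (no
    learning), (N, n_cells).  State is zeroed at the start and carried
    across steps."""
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    state = ModelState.zeros(coder.n_cells)
    out = np.empty((len(trajectory), coder.n_cells))
    for lo in range(0, len(trajectory), chunk):
        hi = min(lo + chunk, len(trajectory))
        I = population.rate_matrix(trajectory.positions[lo:hi],
                                   trajectory.times[lo:hi],
                                   trajectory.headings[lo:hi])
        out[lo:hi], _ = run_section(coder, I, state, learn=False)
    return out


def recover_rate_maps(coder: SparseCodingModel, population: ECPopulation,
                      trajectory: Trajectory, n_bins: int = 40,
                      responses: np.ndarray | None = None) -> list[RateMap]:
    """Recover each cell's rate map as the mean settled response over all
    trajectory samples falling in each bin of the n x n lattice."""
    if responses is None:
        responses = run_inference(coder, population, trajectory)
    size = trajectory.arena_size
    bin_size = size / n_bins
    ix = np.minimum((trajectory.positions[:, 0] / bin_size).astype(int),
                    n_bins - 1)
    iy = np.minimum((trajectory.positions[:, 1] / bin_size).astype(int),
                    n_bins - 1)
    flat = ix * n_bins + iy
    occ = np.bincount(flat, minlength=n_bins * n_bins)
    sums = np.zeros((n_bins * n_bins, coder.n_cells))
    np.add.at(sums, flat, responses)
    occ2 = occ.reshape(n_bins, n_bins)
    maps = []
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / occ[:, None]
    for c in range(coder.n_cells):
        g = means[:, c].reshape(n_bins, n_bins)
        g[occ2 == 0] = 0.0
        maps.append(RateMap(g, occ2.copy(), bin_size))
    return maps


def _bump(params, xy):
    a, cx, cy, r = params
    d2 = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
    return a * np.exp(-_LN5 * d2 / (r * r))


def fit_spatial_field(rate_map: RateMap) -> SpatialFit:
    """Nonlinear least-squares fit of the bump model over visited bins."""
    vis = rate_map.visited
    if vis.sum() < 10:
        raise ValueError("need at least 10 visited bins")
    centers = rate_map.bin_centers()
    X, Y = np.meshgrid(centers, centers, indexing="ij")
    xy = np.column_stack([X[vis], Y[vis]])
    z = rate_map.grid[vis]
    ss = float(np.sum(z * z))
    if ss == 0:
        return SpatialFit(0.0, np.full(2, np.nan), 0.0, 0.0,
                          converged=False)
    k = int(np.argmax(z))
    x0 = (float(z[k]), xy[k, 0], xy[k, 1], 2 * rate_map.bin_size)
    try:
        res = least_squares(
            lambda p: _bump(p, xy) - z, x0,
            bounds=([0, -np.inf, -np.inf, 1e-6],
                    [np.inf, np.inf, np.inf, np.inf]))
    except Exception:
        return SpatialFit(np.nan, np.full(2, np.nan), np.nan, np.inf,
                          converged=False)
    err = float(np.sum(res.fun ** 2) / ss)
    if not res.success:
        return SpatialFit(np.nan, np.full(2, np.nan), np.nan, np.inf,
                          converged=False)
    a, cx, cy, r = res.x
    return SpatialFit(float(a), np.array([cx, cy]), float(r), err)


def select_place_cells(fits, arena_size: float = 1.0,
                       min_radius: float = 0.05,
                       max_error: float = 0.40):
    """Indices of fits passing the place-cell criteria, plus the subset
    whose entire field disc lies inside the arena (the cells eligible for
    precession measurement)."""
    selected, fully_inside = [], []
    for i, f in enumerate(fits):
        if f is None or not f.converged or not np.all(np.isfinite(f.center)):
            continue
        inside = (0 <= f.center[0] <= arena_size
                  and 0 <= f.center[1] <= arena_size)
        if inside and f.radius > min_radius and f.fit_error < max_error:
            selected.append(i)
            if (f.center[0] - f.radius >= 0
                    and f.center[0] + f.radius <= arena_size
                    and f.center[1] - f.radius >= 0
                    and f.center[1] + f.radius <= arena_size):
                fully_inside.append(i)
    return np.array(selected, dtype=int), np.array(fully_inside, dtype=int)


def response_trace_at(coder: SparseCodingModel, population: ECPopulation,
                      r, heading, cell_index=None, duration: float = 1.0,
                      dt: float = 0.01, warmup: float = 0.1):
    """Response over ``duration`` seconds with the rat held at ``r`` with
    fixed ``heading`` while time advances at the trajectory cadence.

    The LCA state settles over a ``warmup`` lead-in at negative times so
    the recorded trace starts at t = 0 (keeping fitted phases comparable
    across positions).  Returns (times, trace) for one cell, or
    (times, all-cell matrix) when ``cell_index`` is None.
    """
    n_warm = int(round(warmup / dt))
    n = int(round(duration / dt))
    times = (np.arange(-n_warm, n) * dt)
    r = np.asarray(r, dtype=float)
    pos = np.broadcast_to(r, (len(times), 2))
    theta = (np.arctan2(heading[1], heading[0]) if np.ndim(heading)
             else float(heading))
    thetas = np.full(len(times), theta)
    I = population.rate_matrix(pos, times, thetas)
    state = ModelState.zeros(coder.n_cells)
    S, _ = run_section(coder, I, state, learn=False)
    S = S[n_warm:]
    t = times[n_warm:]
    if cell_index is None:
        return t, S
    return t, S[:, int(cell_index)]


def _phase_model(params, t):
    a, k, f, phi = params
    return a * np.exp(k * (np.cos(2 * np.pi * f * t - phi) - 1.0))


def fit_temporal_response(times, trace, f0: float = 10.0) -> TemporalFit:
    """Nonlinear least-squares fit of the phase-modulation model to a
    trace; the fitted phase is wrapped to [0, 360) degrees."""
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if np.ptp(times) < 2.0 / f0:
        raise ValueError("trace shorter than two periods of the initial "
                         "frequency guess")
    ss = float(np.sum(trace ** 2))
    peak = float(trace.max(initial=0.0))
    if ss == 0 or peak <= 0 or np.ptp(trace) < 1e-12 * max(peak, 1.0):
        return TemporalFit(peak, 0.0, np.nan, np.nan,
                           0.0 if ss == 0 else np.nan, valid=False)
    phi0 = (2 * np.pi * f0 * times[int(np.argmax(trace))]) % (2 * np.pi)
    x0 = (peak, 1.0, f0, phi0)
    res = least_squares(
        lambda p: _phase_model(p, times) - trace, x0,
        bounds=([0, 0, 5.0, phi0 - np.pi], [np.inf, np.inf, 20.0,
                                            phi0 + np.pi]))
    a, k, f, phi = res.x
    err = float(np.sum(res.fun ** 2) / ss)
    phase_deg = float(np.rad2deg(phi) % 360.0)
    valid = bool(res.success and k > 1e-3)
    return TemporalFit(float(a), float(k), float(f), phase_deg, err,
                       valid=valid)


def normalized_pdcd(r, heading, center, radius) -> float:
    """Normalised projected distance in the current running direction:
    0 at field entry, 1 at exit, along the chord through ``r``."""
    r = np.asarray(r, dtype=float)
    center = np.asarray(center, dtype=float)
    u = np.asarray(heading, dtype=float)
    u = u / np.hypot(u[0], u[1])
    delta = r - center
    d = float(delta @ u)
    c = float(-delta[0] * u[1] + delta[1] * u[0])
    rp2 = radius * radius - c * c
    if rp2 <= 0:
        raise DegenerateChordError("running line tangent to the field")
    rp = np.sqrt(rp2)
    return (d + rp) / (2.0 * rp)


def measure_precession(coder: SparseCodingModel, population: ECPopulation,
                       cell_index: int, fit: SpatialFit, seed=None,
                       sigma_theta: float = 1.0, mean_speed: float = 0.30,
                       straight: bool = False, min_samples: int = 5,
                       max_retries: int = 20) -> PrecessionSummary:
    """Phase precession of one place cell along a field traversal.

    A trajectory starts at the left edge of the fitted field at centre
    height, heading east (``straight=True`` suppresses the heading
    noise).  At each 10 ms position inside the fitted disc the 1 s
    response trace is fitted; entry/exit phases are the first/last valid
    fits and the correlation is the Pearson r of (normalised pdcd,
    phase).  A series crossing the 0/360 boundary is flagged ``wrapped``
    and its correlation reported as nan.
    """
    center, radius = fit.center, fit.radius
    rng = np.random.default_rng(seed)
    duration = 6.0 * radius / mean_speed
    for attempt in range(max_retries):
        params = TrajectoryParams(
            sigma_theta=0.0 if straight else sigma_theta,
            mean_speed=mean_speed, duration=duration,
            arena_size=population.arena_size,
            speed_noise=0.0 if straight else 0.08,
            seed=int(rng.integers(2**31)),
            start=(max(center[0] - radius, 0.0), center[1]),
            start_heading=0.0)
        traj = simulate_trajectory(params)
        d2 = ((traj.positions - center) ** 2).sum(axis=1)
        inside = d2 < radius * radius
        if inside.sum() >= min_samples:
            break
    else:
        raise RuntimeError("no traversal with enough in-field samples")

    idx = np.nonzero(inside)[0]
    pdcd, phases = [], []
    for k in idx:
        r = traj.positions[k]
        heading = (np.cos(traj.headings[k]), np.sin(traj.headings[k]))
        try:
            x = normalized_pdcd(r, heading, center, radius)
        except DegenerateChordError:
            continue
        t, trace = response_trace_at(coder, population, r, heading,
                                     cell_index=cell_index)
        tf = fit_temporal_response(t, trace)
        if not tf.valid:
            continue
        pdcd.append(x)
        phases.append(tf.phase)
    pdcd = np.asarray(pdcd)
    phases = np.asarray(phases)
    if len(phases) < 2 or np.ptp(phases) < 1e-9:
        return PrecessionSummary(pdcd, phases,
                                 phases[0] if len(phases) else np.nan,
                                 phases[-1] if len(phases) else np.nan,
                                 np.nan)
    wrapped = bool(np.any(np.diff(phases) > 180.0))
    corr = np.nan if wrapped else float(pearsonr(pdcd, phases)[0])
    return PrecessionSummary(pdcd, phases, float(phases[0]),
                             float(phases[-1]), corr, wrapped=wrapped)
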