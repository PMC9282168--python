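"""Entorhinal input populations: spatiotemporal grid cells and weakly
spatial cells.

A grid cell fires over a hexagonal lattice of circular fields.  Within a
field centred at ``r_c`` the rate is the product of a spatial envelope

    f_s(r) = alpha_c * exp(-ln5 * ||r - r_c||^2 / R^2),   R = 0.32 * lambda,

truncated at distance ``R``, and a theta-phase modulation

    f_phi(r, t) = exp(k_phi * (cos(2 pi F t - phi(r)) - 1)),

where the firing phase ``phi(r)`` falls linearly with the projected
distance along the current running direction (pdcd): with d the signed
projection of ``r - r_c`` onto the heading and R' the half-length of the
chord through ``r`` along the heading,

    phi(r) = phi_0 - delta_phi * (d + R') / (2 R').

A traversal therefore shows perfect phase precession (phase vs pdcd
correlation -1).  Weakly spatial cells are smoothed-noise rate maps with
values in [0, 0.1] and carry no temporal structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ._kernels import grid_rates_kernel

__all__ = [
    "GridModuleSpec",
    "DEFAULT_GRID_MODULES",
    "GridCellParams",
    "WeaklySpatialCell",
    "ECPopulation",
    "sample_grid_population",
    "grid_spatial_rate",
    "grid_phase",
    "grid_response",
    "make_weakly_spatial_cells",
    "ec_rates",
    "save_population",
    "load_population",
]

_LN5 = np.log(5.0)
FIELD_RADIUS_RATIO = 0.32      # R = 0.32 * spacing
THETA_FREQUENCY = 10.0         # Hz


class OutOfFieldError(ValueError):
    """Query position lies outside every firing field of the cell."""


class DegenerateChordError(ValueError):
    """The running line is tangent to the field boundary (R' = 0)."""


@dataclass(frozen=True)
class GridModuleSpec:
    """One grid module: shared mean spacing/orientation and population share."""

    mean_spacing: float            # m
    mean_orientation: float        # deg
    fraction: float                # share of the grid population
    spacing_sd: float = 0.08       # m
    orientation_sd: float = 3.0    # deg


#: The four grid modules used throughout: mean spacings 38.8, 48.4, 65 and
#: 98.4 cm, orientations 15/30/45/0 degrees, covering 43.5/43.5/6.5/6.5%
#: of the grid population.
DEFAULT_GRID_MODULES = (
    GridModuleSpec(0.388, 15.0, 0.435),
    GridModuleSpec(0.484, 30.0, 0.435),
    GridModuleSpec(0.650, 45.0, 0.065),
    GridModuleSpec(0.984, 0.0, 0.065),
)


@dataclass
class GridCellParams:
    """Full parameterisation of one spatiotemporal grid cell.

    The field lattice is spanned by basis vectors of length ``spacing`` at
    ``orientation`` and ``orientation + 60 deg``; ``amplitudes`` holds the
    per-field peak rates on the (ni x nj) index window [i0, i0+ni) x
    [j0, j0+nj), with non-positive entries marking vertices dropped for
    lying outside the arena margin.
    """

    spacing: float                 # lattice constant lambda, m
    orientation: float             # deg
    offset: np.ndarray             # (2,), m
    k_phi: float                   # phase-modulation depth
    phi0: float                    # entry phase, deg
    delta_phi: float               # phase change across a field, deg
    freq: float = THETA_FREQUENCY  # theta frequency, Hz
    i0: int = 0
    j0: int = 0
    amplitudes: np.ndarray = field(default=None)  # (ni, nj)
    module_index: int = -1         # grid module this cell was drawn from

    @property
    def radius(self) -> float:
        """Field radius R = 0.32 * spacing (fields never overlap)."""
        return FIELD_RADIUS_RATIO * self.spacing

    @property
    def basis(self) -> np.ndarray:
        """Columns are the two lattice vectors."""
        th = np.deg2rad(self.orientation)
        return self.spacing * np.array(
            [[np.cos(th), np.cos(th + np.pi / 3)],
             [np.sin(th), np.sin(th + np.pi / 3)]])

    def field_centers(self) -> np.ndarray:
        """Positions of the retained (in-margin) field centres, (K, 2)."""
        B = self.basis
        ii, jj = np.nonzero(self.amplitudes > 0)
        idx = np.column_stack([ii + self.i0, jj + self.j0]).astype(float)
        return idx @ B.T + self.offset

    def field_amplitudes(self) -> np.ndarray:
        return self.amplitudes[self.amplitudes > 0]

    def nearest_field(self, r) -> tuple[np.ndarray, float]:
        """Nearest lattice vertex to ``r`` and its amplitude (0 if the
        vertex was not retained)."""
        r = np.asarray(r, dtype=float)
        B = self.basis
        frac = np.linalg.solve(B, r - self.offset)
        base = np.floor(frac).astype(int)
        cand = base + np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        verts = cand @ B.T + self.offset
        k = int(np.argmin(((verts - r) ** 2).sum(axis=1)))
        i, j = cand[k] - (self.i0, self.j0)
        ni, nj = self.amplitudes.shape
        amp = (float(self.amplitudes[i, j])
               if 0 <= i < ni and 0 <= j < nj else 0.0)
        return verts[k], max(amp, 0.0)


def _make_lattice_amplitudes(spacing, orientation, offset, arena_size,
                             rng) -> tuple[int, int, np.ndarray]:
    """Enumerate lattice vertices within the arena expanded by R and draw
    their per-field amplitudes ~ N(1, 0.1); dropped vertices get -1."""
    R = FIELD_RADIUS_RATIO * spacing
    th = np.deg2rad(orientation)
    B = spacing * np.array([[np.cos(th), np.cos(th + np.pi / 3)],
                            [np.sin(th), np.sin(th + np.pi / 3)]])
    lo, hi = -R, arena_size + R
    corners = np.array([[lo, lo], [lo, hi], [hi, lo], [hi, hi]])
    frac = np.linalg.solve(B, (corners - offset).T).T
    i_lo, j_lo = np.floor(frac.min(axis=0)).astype(int) - 1
    i_hi, j_hi = np.ceil(frac.max(axis=0)).astype(int) + 1
    ii = np.arange(i_lo, i_hi + 1)
    jj = np.arange(j_lo, j_hi + 1)
    I, J = np.meshgrid(ii, jj, indexing="ij")
    verts = np.stack([I, J], axis=-1) @ B.T + offset
    inside = ((verts[..., 0] >= lo) & (verts[..., 0] <= hi)
              & (verts[..., 1] >= lo) & (verts[..., 1] <= hi))
    amps = np.full(I.shape, -1.0)
    n_in = int(inside.sum())
    drawn = rng.normal(1.0, 0.1, size=n_in)
    # amplitudes are peak rates; redraw the (very rare) non-positive ones
    bad = drawn <= 0
    while bad.any():
        drawn[bad] = rng.normal(1.0, 0.1, size=int(bad.sum()))
        bad = drawn <= 0
    amps[inside] = drawn
    return int(i_lo), int(j_lo), amps


def sample_grid_population(n_cells: int,
                           modules=DEFAULT_GRID_MODULES,
                           phase_ranges=((0.8, 1.2), (300.0, 340.0),
                                         (300.0, 340.0)),
                           seed=None,
                           arena_size: float = 1.0) -> list[GridCellParams]:
    """Draw a grid-cell population.

    Each cell joins a module with the module's population fraction; its
    spacing ~ N(mean, 8 cm) (negative draws resampled), orientation ~
    N(mean, 3 deg), offset ~ U[0, spacing)^2, per-field amplitudes ~
    N(1, 0.1).  ``phase_ranges`` gives the uniform ranges of (k_phi,
    phi_0, delta_phi); theta frequency is 10 Hz.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    modules = list(modules)
    if not modules:
        raise ValueError("at least one grid module is required")
    fractions = np.array([m.fraction for m in modules])
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("module fractions must sum to 1")
    rng = np.random.default_rng(seed)
    (k_lo, k_hi), (p_lo, p_hi), (d_lo, d_hi) = phase_ranges
    assignments = rng.choice(len(modules), size=n_cells, p=fractions)
    cells = []
    for mod_idx in assignments:
        mod = modules[mod_idx]
        spacing = rng.normal(mod.mean_spacing, mod.spacing_sd)
        while spacing <= 0:
            spacing = rng.normal(mod.mean_spacing, mod.spacing_sd)
        orientation = rng.normal(mod.mean_orientation, mod.orientation_sd)
        offset = rng.uniform(0.0, spacing, size=2)
        i0, j0, amps = _make_lattice_amplitudes(
            spacing, orientation, offset, arena_size, rng)
        cells.append(GridCellParams(
            spacing=spacing, orientation=orientation, offset=offset,
            k_phi=rng.uniform(k_lo, k_hi), phi0=rng.uniform(p_lo, p_hi),
            delta_phi=rng.uniform(d_lo, d_hi),
            i0=i0, j0=j0, amplitudes=amps, module_index=int(mod_idx)))
    return cells


def grid_spatial_rate(cell: GridCellParams, r) -> float:
    """Spatial envelope at ``r``: alpha_c exp(-ln5 d^2/R^2) inside the
    nearest field, 0 beyond distance R of every field centre."""
    center, amp = cell.nearest_field(r)
    if amp <= 0:
        return 0.0
    d2 = float(((np.asarray(r, float) - center) ** 2).sum())
    R2 = cell.radius ** 2
    if d2 >= R2:
        return 0.0
    return amp * np.exp(-_LN5 * d2 / R2)


def _chord_phase(delta, heading, radius, phi0, delta_phi) -> float:
    """Phase (deg, unwrapped) from the chord geometry; ``delta`` is the
    displacement from the field centre."""
    u = np.asarray(heading, dtype=float)
    nrm = np.hypot(u[0], u[1])
    if nrm == 0:
        raise ValueError("heading must be a non-zero vector")
    u = u / nrm
    d = delta[0] * u[0] + delta[1] * u[1]
    c = -delta[0] * u[1] + delta[1] * u[0]
    rp2 = radius * radius - c * c
    if rp2 <= 0:
        raise DegenerateChordError("running line tangent to the field")
    rp = np.sqrt(rp2)
    return phi0 - delta_phi * (d + rp) / (2.0 * rp)


def grid_phase(cell: GridCellParams, r, heading) -> float:
    """Firing phase (deg, in [0, 360)) at ``r`` for the given running
    direction; raises if ``r`` lies outside every field."""
    center, amp = cell.nearest_field(r)
    delta = np.asarray(r, float) - center
    if amp <= 0 or (delta ** 2).sum() >= cell.radius ** 2:
        raise OutOfFieldError("position outside every firing field")
    return _chord_phase(delta, heading, cell.radius, cell.phi0,
                        cell.delta_phi) % 360.0


def grid_response(cell: GridCellParams, r, t: float, heading) -> float:
    """Full spatiotemporal rate f(r,t) = f_s(r) * f_phi(r,t); 0 outside
    all fields."""
    center, amp = cell.nearest_field(r)
    delta = np.asarray(r, float) - center
    d2 = float((delta ** 2).sum())
    R2 = cell.radius ** 2
    if amp <= 0 or d2 >= R2:
        return 0.0
    fs = amp * np.exp(-_LN5 * d2 / R2)
    phi = np.deg2rad(_chord_phase(delta, heading, cell.radius, cell.phi0,
                                  cell.delta_phi))
    return fs * np.exp(cell.k_phi
                       * (np.cos(2 * np.pi * cell.freq * t - phi) - 1.0))


@dataclass
class WeaklySpatialCell:
    """Smoothed-noise rate map on a regular lattice, values in [0, 0.1],
    evaluated by bilinear interpolation."""

    lattice: np.ndarray       # (res, res), lattice[i, j] = rate at (x_i, y_j)
    arena_size: float = 1.0

    def rate(self, r) -> float:
        x, y = np.asarray(r, dtype=float)
        res = self.lattice.shape[0]
        gx = np.clip(x / self.arena_size, 0, 1) * (res - 1)
        gy = np.clip(y / self.arena_size, 0, 1) * (res - 1)
        x0, y0 = int(min(gx, res - 2)), int(min(gy, res - 2))
        fx, fy = gx - x0, gy - y0
        z = self.lattice
        return float((1 - fx) * (1 - fy) * z[x0, y0]
                     + fx * (1 - fy) * z[x0 + 1, y0]
                     + (1 - fx) * fy * z[x0, y0 + 1]
                     + fx * fy * z[x0 + 1, y0 + 1])


def make_weakly_spatial_cells(n_cells: int,
                              lattice_resolution: int = 100,
                              smoothing_sigma: float = 0.06,
                              seed=None,
                              arena_size: float = 1.0,
                              max_rate: float = 0.1):
    """Build weakly spatial cells: i.i.d. U(0,1) lattice noise, Gaussian
    smoothing (sigma = 6 cm, reflective boundary), affine rescale to
    [0, max_rate]."""
    spacing = arena_size / (lattice_resolution - 1)
    if smoothing_sigma < 2 * spacing:
        raise ValueError("lattice too coarse for the smoothing scale")
    rng = np.random.default_rng(seed)
    sigma_px = smoothing_sigma / spacing
    cells = []
    for _ in range(n_cells):
        noise = rng.uniform(0.0, 1.0,
                            size=(lattice_resolution, lattice_resolution))
        sm = gaussian_filter(noise, sigma=sigma_px, mode="reflect")
        sm -= sm.min()
        peak = sm.max()
        if peak > 0:
            sm *= max_rate / peak
        cells.append(WeaklySpatialCell(sm, arena_size=arena_size))
    return cells


class ECPopulation:
    """Ordered EC input population: weakly spatial cells first, then grid
    cells.  The ordering is fixed for the life of a model; the input
    vector ``I`` concatenates the two blocks in that order."""

    def __init__(self, grid_cells, weakly_spatial=(), arena_size: float = 1.0):
        self.grid_cells = list(grid_cells)
        self.weakly_spatial = list(weakly_spatial)
        self.arena_size = arena_size
        self._pack = None
        self._weak_stack = (np.stack([c.lattice for c in self.weakly_spatial])
                            if self.weakly_spatial else None)

    @property
    def n_weak(self) -> int:
        return len(self.weakly_spatial)

    @property
    def n_grid(self) -> int:
        return len(self.grid_cells)

    @property
    def n_inputs(self) -> int:
        return self.n_weak + self.n_grid

    @property
    def grid_rows(self) -> np.ndarray:
        """Row indices of the grid block in the input vector."""
        return np.arange(self.n_weak, self.n_inputs)

    def _packed(self):
        if self._pack is None:
            cells = self.grid_cells
            C = len(cells)
            off = np.empty((C, 2))
            basis = np.empty((C, 4))
            inv = np.empty((C, 4))
            r2 = np.empty(C)
            kphi = np.empty(C)
            phi0 = np.empty(C)
            dphi = np.empty(C)
            freq = np.empty(C)
            i0 = np.empty(C, dtype=np.int64)
            j0 = np.empty(C, dtype=np.int64)
            ni = np.empty(C, dtype=np.int64)
            nj = np.empty(C, dtype=np.int64)
            amp_start = np.zeros(C + 1, dtype=np.int64)
            amp_list = []
            for c, cell in enumerate(cells):
                off[c] = cell.offset
                B = cell.basis
                basis[c] = B.ravel()
                inv[c] = np.linalg.inv(B).ravel()
                r2[c] = cell.radius ** 2
                kphi[c] = cell.k_phi
                phi0[c] = cell.phi0
                dphi[c] = cell.delta_phi
                freq[c] = cell.freq
                i0[c] = cell.i0
                j0[c] = cell.j0
                ni[c], nj[c] = cell.amplitudes.shape
                amp_list.append(cell.amplitudes.ravel())
                amp_start[c + 1] = amp_start[c] + cell.amplitudes.size
            amps = (np.concatenate(amp_list) if amp_list
                    else np.empty(0))
            self._pack = (off, basis, inv, r2, kphi, phi0, dphi, freq,
                          i0, j0, ni, nj, amp_start, amps)
        return self._pack

    def grid_rate_matrix(self, positions, times, headings) -> np.ndarray:
        """Rates of all grid cells along a path, (N, n_grid)."""
        positions = np.ascontiguousarray(positions, dtype=np.float64)
        times = np.ascontiguousarray(times, dtype=np.float64)
        headings = np.ascontiguousarray(headings, dtype=np.float64)
        out = np.empty((positions.shape[0], self.n_grid))
        if self.n_grid:
            grid_rates_kernel(positions, times, headings, *self._packed(),
                              out)
        return out

    def weak_rate_matrix(self, positions) -> np.ndarray:
        """Rates of all weakly spatial cells along a path, (N, n_weak)."""
        n = len(positions)
        if not self.n_weak:
            return np.empty((n, 0))
        res = self._weak_stack.shape[1]
        g = np.clip(np.asarray(positions, float) / self.arena_size, 0, 1) \
            * (res - 1)
        base = np.minimum(g.astype(int), res - 2)
        f = g - base
        x0, y0 = base[:, 0], base[:, 1]
        fx, fy = f[:, 0][:, None], f[:, 1][:, None]
        z = self._weak_stack
        out = ((1 - fx) * (1 - fy) * z[:, x0, y0].T
               + fx * (1 - fy) * z[:, x0 + 1, y0].T
               + (1 - fx) * fy * z[:, x0, y0 + 1].T
               + fx * fy * z[:, x0 + 1, y0 + 1].T)
        return out

    def rate_matrix(self, positions, times, headings) -> np.ndarray:
        """Input matrix I along a path, (N, n_inputs): weak block first."""
        return np.hstack([self.weak_rate_matrix(positions),
                          self.grid_rate_matrix(positions, times, headings)])

    def rates(self, r, t: float, heading) -> np.ndarray:
        """Input vector I at one (position, time, heading)."""
        r = np.asarray(r, dtype=float)
        if not (0 <= r[0] <= self.arena_size and 0 <= r[1] <= self.arena_size):
            raise ValueError("position outside the arena")
        theta = (np.arctan2(heading[1], heading[0])
                 if np.ndim(heading) else float(heading))
        return self.rate_matrix(r[None, :], np.array([t]),
                                np.array([theta]))[0]


def ec_rates(pop: ECPopulation, r, t: float, heading) -> np.ndarray:
    """Functional alias of :meth:`ECPopulation.rates`."""
    return pop.rates(r, t, heading)


def save_population(pop: ECPopulation, path) -> None:
    """Serialise a population to an ``.npz`` container (one record per
    cell: lattice geometry, amplitude window, phase parameters)."""
    C = pop.n_grid
    scal = np.empty((C, 9))
    windows = []
    for c, cell in enumerate(pop.grid_cells):
        scal[c] = (cell.spacing, cell.orientation, cell.offset[0],
                   cell.offset[1], cell.k_phi, cell.phi0, cell.delta_phi,
                   cell.freq, cell.module_index)
        windows.append((cell.i0, cell.j0) + cell.amplitudes.shape)
    arrs = {
        "scalars": scal,
        "windows": np.asarray(windows, dtype=np.int64).reshape(C, 4),
        "amps": (np.concatenate([c.amplitudes.ravel()
                                 for c in pop.grid_cells])
                 if C else np.empty(0)),
        "arena_size": np.array(pop.arena_size),
    }
    if pop.n_weak:
        arrs["weak"] = np.stack([c.lattice for c in pop.weakly_spatial])
    np.savez_compressed(path, **arrs)


def load_population(path) -> ECPopulation:
    with np.load(path) as z:
        scal = z["scalars"]
        win = z["windows"]
        amps = z["amps"]
        arena = float(z["arena_size"])
        weak_stack = z["weak"] if "weak" in z.files else None
    cells = []
    start = 0
    for c in range(scal.shape[0]):
        i0, j0, ni, nj = win[c]
        a = amps[start:start + ni * nj].reshape(ni, nj)
        start += ni * nj
        cells.append(GridCellParams(
            spacing=scal[c, 0], orientation=scal[c, 1],
            offset=scal[c, 2:4].copy(), k_phi=scal[c, 4], phi0=scal[c, 5],
            delta_phi=scal[c, 6], freq=scal[c, 7],
            i0=int(i0), j0=int(j0), amplitudes=a,
            module_index=int(scal[c, 8])))
    weak = ([WeaklySpatialCell(weak_stack[i], arena_size=arena)
             for i in range(weak_stack.shape[0])]
            if weak_stack is not None else [])
    return ECPopulation(cells, weak, arena_size=arena)
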