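"""Model and results objects tying the pieces together.

``PlaceCellModel`` couples an EC input population to a bank of
hippocampal model cells through non-negative sparse coding; ``fit()``
runs the dictionary learning along a foraging trajectory and returns a
``PlaceCellResults`` carrying the learned dictionary together with the
receptive-field recovery, fitting, selection and precession analyses.
"""

from __future__ import annotations

import numpy as np

from . import analysis as _an
from .ec import ECPopulation
from .sparse import (ModelState, SparseCodingModel, inactivate_inputs,
                     init_model, run_section)
from .trajectory import Trajectory

__all__ = ["PlaceCellModel", "PlaceCellResults"]


class PlaceCellModel:
    """Sparse-coding model of hippocampal place-cell learning.

    Parameters
    ----------
    population : ECPopulation
        The EC input cells (weakly spatial block first, then grid cells).
    n_cells : int
        Number of hippocampal model cells (dictionary columns).
    seed : int or None
        Seed for the dictionary initialisation.
    tau, beta, dt_model, n_inner, eta
        LCA dynamics and learning constants (see ``SparseCodingModel``).
    carry_state : bool
        Whether the membrane state carries over between trajectory steps
        within a session (default True; reset happens at session start).
    """

    def __init__(self, population: ECPopulation, n_cells: int = 100,
                 seed=None, tau: float = 0.010, beta: float = 0.3,
                 dt_model: float = 0.0002, n_inner: int = 50,
                 eta: float = 0.01, carry_state: bool = True):
        self.population = population
        self.n_cells = n_cells
        self.carry_state = carry_state
        self.coder = init_model(population.n_inputs, n_cells, seed=seed,
                                tau=tau, beta=beta, dt_model=dt_model,
                                n_inner=n_inner, eta=eta)

    def fit(self, trajectory: Trajectory, chunk: int = 4000,
            log_every: float = 60.0, verbose: bool = False
            ) -> "PlaceCellResults":
        """Learn the dictionary along a training trajectory.

        The trajectory advances in 10 ms steps; each step runs the LCA
        iterations and one Hebbian dictionary update.  ``log_every``
        seconds of simulated time, the running mean squared
        reconstruction error ||I - A s||^2 is recorded.
        """
        coder = self.coder
        state = ModelState.zeros(coder.n_cells)
        n = len(trajectory)
        err_log, err_times = [], []
        acc, count, next_log = 0.0, 0, log_every
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            I = self.population.rate_matrix(trajectory.positions[lo:hi],
                                            trajectory.times[lo:hi],
                                            trajectory.headings[lo:hi])
            if not self.carry_state:
                state = ModelState.zeros(coder.n_cells)
            _, err = run_section(coder, I, state, learn=True)
            acc += float(err.sum())
            count += len(err)
            while next_log <= trajectory.times[hi - 1]:
                err_log.append(acc / count if count else np.nan)
                err_times.append(next_log)
                acc, count = 0.0, 0
                next_log += log_every
                if verbose:
                    print(f"t={err_times[-1]:7.0f}s  "
                          f"recon_err={err_log[-1]:.5f}")
        return PlaceCellResults(self, coder,
                                np.asarray(err_times), np.asarray(err_log))


class PlaceCellResults:
    """Learned dictionary plus the downstream analyses.

    Analyses are computed lazily from a test trajectory passed to
    ``analyze`` (or to the individual methods) and cached.
    """

    def __init__(self, model: PlaceCellModel, coder: SparseCodingModel,
                 err_times=None, err_log=None):
        self.model = model
        self.population = model.population
        self.coder = coder
        self.recon_err_times = err_times
        self.recon_err = err_log
        self._maps = None
        self._fits = None
        self._selection = None

    @property
    def A(self) -> np.ndarray:
        return self.coder.A

    # -- lesion ----------------------------------------------------------
    def inactivate_grid(self) -> "PlaceCellResults":
        """Zero the grid-cell rows of the dictionary (columns
        renormalised, learning disabled) — the MEC-inactivation
        experiment.  Returns a new results object."""
        coder = inactivate_inputs(self.coder, self.population.grid_rows)
        return PlaceCellResults(self.model, coder)

    # -- analyses --------------------------------------------------------
    def recover_rate_maps(self, trajectory: Trajectory, n_bins: int = 40):
        self._maps = _an.recover_rate_maps(self.coder, self.population,
                                           trajectory, n_bins=n_bins)
        self._fits = None
        self._selection = None
        return self._maps

    @property
    def rate_maps(self):
        if self._maps is None:
            raise RuntimeError("call recover_rate_maps(test_trajectory) "
                               "first")
        return self._maps

    def spatial_fits(self):
        if self._fits is None:
            fits = []
            for m in self.rate_maps:
                try:
                    fits.append(_an.fit_spatial_field(m))
                except ValueError:
                    fits.append(None)
            self._fits = fits
        return self._fits

    def place_cells(self):
        """(selected indices, subset with field fully inside the arena)."""
        if self._selection is None:
            self._selection = _an.select_place_cells(
                self.spatial_fits(), self.population.arena_size)
        return self._selection

    def precession(self, cell_index: int, seed=None, straight=False):
        fit = self.spatial_fits()[cell_index]
        return _an.measure_precession(self.coder, self.population,
                                      cell_index, fit, seed=seed,
                                      straight=straight)

    def response_trace(self, r, heading, cell_index, duration=1.0):
        return _an.response_trace_at(self.coder, self.population, r,
                                     heading, cell_index=cell_index,
                                     duration=duration)

    def analyze(self, trajectory: Trajectory):
        """Run map recovery, fitting and selection in one call."""
        self.recover_rate_maps(trajectory)
        self.spatial_fits()
        return self.place_cells()

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        lines = ["Place-cell model results",
                 "=" * 40,
                 f"inputs: {self.population.n_weak} weakly spatial + "
                 f"{self.population.n_grid} grid cells",
                 f"hippocampal cells: {self.coder.n_cells}",
                 f"learning enabled: {self.coder.learning_enabled}"]
        if self.recon_err is not None and len(self.recon_err):
            lines.append(f"final reconstruction error: "
                         f"{self.recon_err[-1]:.5f}")
        if self._fits is not None:
            sel, inside = self.place_cells()
            radii = [self._fits[i].radius for i in sel]
            lines += [
                f"place cells: {len(sel)} / {self.coder.n_cells}",
                f"  with field fully inside arena: {len(inside)}",
            ]
            if radii:
                lines.append(f"mean field radius: "
                             f"{100 * float(np.mean(radii)):.2f} cm")
        return "\n".join(lines)
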