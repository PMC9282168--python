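"""Scenario orchestration.

Three scenarios mirror the lesion logic of the underlying experiment:

1. grid-cell input only (900 cells) — place fields and phase precession
   are learned from spatiotemporal grid input;
2. grid cells plus 400 weakly spatial cells;
3. the scenario-2 model with the grid rows of the dictionary zeroed
   (columns renormalised, learning off) — place fields persist on the
   weakly spatial input alone.

A master seed deterministically spawns independent streams for the
training trajectory, the test trajectory, the EC population, the
dictionary initialisation and the measurement trajectories, so runs are
bit-reproducible and stages can be swapped independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ec import (ECPopulation, make_weakly_spatial_cells,
                 sample_grid_population)
from .model import PlaceCellModel, PlaceCellResults
from .trajectory import TrajectoryParams, simulate_trajectory

__all__ = ["ScenarioConfig", "ScenarioReport", "run_scenario",
           "compare_scenarios", "spawn_seed"]

_STREAMS = ("train_trajectory", "test_trajectory", "grid_cells",
            "weak_cells", "dictionary", "measurement")


def spawn_seed(master_seed: int, stream: str) -> int:
    """Derive an independent 31-bit stream seed from the master seed."""
    idx = _STREAMS.index(stream)
    return int(np.random.SeedSequence([int(master_seed), idx])
               .generate_state(1)[0] % (2 ** 31))


@dataclass
class ScenarioConfig:
    scenario: int = 1
    n_hippocampal: int = 100
    n_grid: int = 900
    n_weak: int = 0                      # 400 in scenarios 2 and 3
    train_duration: float = 3600.0       # s
    test_duration: float = 1200.0        # s
    master_seed: int = 0
    arena_size: float = 1.0
    trajectory: TrajectoryParams = field(
        default_factory=TrajectoryParams)  # template; duration/seed replaced
    measure_precession: bool = True
    verbose: bool = False

    def __post_init__(self):
        if self.scenario not in (1, 2, 3):
            raise ValueError("scenario must be 1, 2 or 3")
        if self.scenario in (2, 3) and self.n_weak == 0:
            self.n_weak = 400


@dataclass
class ScenarioReport:
    """Machine-readable outcome of one scenario run."""

    config: ScenarioConfig
    results: PlaceCellResults
    place_cells: np.ndarray        # selected indices
    fully_inside: np.ndarray       # subset with entire field in the arena
    centers: np.ndarray            # (n_selected, 2), m
    radii_cm: np.ndarray           # (n_selected,), cm
    entry_phases: np.ndarray       # deg, one per analyzed cell
    exit_phases: np.ndarray
    correlations: np.ndarray
    analyzed_cells: np.ndarray     # indices behind the phase statistics

    @property
    def n_place_cells(self) -> int:
        return len(self.place_cells)

    @property
    def mean_radius_cm(self) -> float:
        return float(np.mean(self.radii_cm)) if len(self.radii_cm) else np.nan

    def summary(self) -> str:
        cfg = self.config
        lines = [f"Scenario {cfg.scenario} "
                 f"({cfg.n_weak} weak + {cfg.n_grid} grid inputs, "
                 f"{cfg.train_duration:.0f}s training)",
                 f"place cells: {self.n_place_cells} / {cfg.n_hippocampal}",
                 f"  fields fully inside arena: {len(self.fully_inside)}",
                 f"mean field radius: {self.mean_radius_cm:.2f} cm"]
        good = self.correlations[np.isfinite(self.correlations)]
        if len(good):
            lines += [f"analyzed traversals: {len(good)}",
                      f"median phase-pdcd correlation: "
                      f"{np.median(good):.3f}",
                      f"mean entry/exit phase: "
                      f"{np.mean(self.entry_phases):.1f} / "
                      f"{np.mean(self.exit_phases):.1f} deg"]
        return "\n".join(lines)


def build_population(config: ScenarioConfig) -> ECPopulation:
    grid = sample_grid_population(config.n_grid,
                                  seed=spawn_seed(config.master_seed,
                                                  "grid_cells"),
                                  arena_size=config.arena_size)
    weak = (make_weakly_spatial_cells(config.n_weak,
                                      seed=spawn_seed(config.master_seed,
                                                      "weak_cells"),
                                      arena_size=config.arena_size)
            if config.n_weak else [])
    return ECPopulation(grid, weak, arena_size=config.arena_size)


def _trajectory(config: ScenarioConfig, stream: str, duration: float):
    params = replace(config.trajectory, duration=duration,
                     arena_size=config.arena_size,
                     seed=spawn_seed(config.master_seed, stream))
    return simulate_trajectory(params)


def run_scenario(config: ScenarioConfig,
                 scenario2_results: PlaceCellResults | None = None,
                 population: ECPopulation | None = None) -> ScenarioReport:
    """Run one scenario end to end: build the EC population, train (or,
    for scenario 3, inactivate the grid rows of a scenario-2 model),
    recover rate maps on the test trajectory, fit and select place
    fields, and measure phase precession for the analyzable cells."""
    if config.scenario == 3:
        if scenario2_results is None:
            raise ValueError("scenario 3 requires a scenario-2 result")
        results = scenario2_results.inactivate_grid()
    else:
        if population is None:
            population = build_population(config)
        model = PlaceCellModel(population, n_cells=config.n_hippocampal,
                               seed=spawn_seed(config.master_seed,
                                               "dictionary"))
        if config.train_duration > 0:
            train = _trajectory(config, "train_trajectory",
                                config.train_duration)
            results = model.fit(train, verbose=config.verbose)
        else:
            # untrained control: keep the random dictionary
            results = PlaceCellResults(model, model.coder)

    test = _trajectory(config, "test_trajectory", config.test_duration)
    selected, fully_inside = results.analyze(test)
    fits = results.spatial_fits()
    centers = np.array([fits[i].center for i in selected]).reshape(-1, 2)
    radii_cm = np.array([100.0 * fits[i].radius for i in selected])

    entries, exits, corrs, analyzed = [], [], [], []
    if config.measure_precession:
        meas_seed = spawn_seed(config.master_seed, "measurement")
        for k, i in enumerate(fully_inside):
            try:
                p = results.precession(int(i), seed=meas_seed + k)
            except RuntimeError:
                continue
            if len(p.phases) == 0:
                continue
            analyzed.append(i)
            entries.append(p.entry_phase)
            exits.append(p.exit_phase)
            corrs.append(p.correlation)

    return ScenarioReport(config, results, selected, fully_inside,
                          centers, radii_cm,
                          np.asarray(entries), np.asarray(exits),
                          np.asarray(corrs),
                          np.asarray(analyzed, dtype=int))


def compare_scenarios(report2: ScenarioReport, report3: ScenarioReport):
    """Field-stability table across grid inactivation.

    Returns a dict with per-cell radius changes and centre shifts for the
    cells that are place cells in both reports, the mean changes, and
    whether the scenario-3 place-cell set is a subset of scenario 2's.
    """
    if report2.config.n_hippocampal != report3.config.n_hippocampal:
        raise ValueError("reports index different populations")
    set2 = {int(i): k for k, i in enumerate(report2.place_cells)}
    common, dradius, dcenter = [], [], []
    for k3, i in enumerate(report3.place_cells):
        k2 = set2.get(int(i))
        if k2 is None:
            continue
        common.append(int(i))
        dradius.append(report3.radii_cm[k3] - report2.radii_cm[k2])
        dcenter.append(np.linalg.norm(report3.centers[k3]
                                      - report2.centers[k2]))
    subset = set(map(int, report3.place_cells)) <= set(
        map(int, report2.place_cells))
    return {
        "cells": np.asarray(common, dtype=int),
        "radius_change_cm": np.asarray(dradius),
        "center_shift_m": np.asarray(dcenter),
        "mean_radius_change_cm": (float(np.mean(dradius)) if dradius
                                  else np.nan),
        "mean_center_shift_m": (float(np.mean(dcenter)) if dcenter
                                else np.nan),
        "scenario3_subset_of_scenario2": subset,
    }
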