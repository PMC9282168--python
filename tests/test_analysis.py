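import numpy as np
import pytest

import thetaplace.analysis as an
from thetaplace.analysis import (RateMap, SpatialFit, fit_spatial_field,
                                 fit_temporal_response, normalized_pdcd,
                                 recover_rate_maps, select_place_cells)
from thetaplace.ec import DegenerateChordError, ECPopulation
from thetaplace.sparse import init_model
from thetaplace.trajectory import Trajectory

LN5 = np.log(5.0)


def bump_map(amplitude, center, radius, n_bins=40, bin_size=0.025,
             noise_sd=0.0, rng=None):
    centers = (np.arange(n_bins) + 0.5) * bin_size
    X, Y = np.meshgrid(centers, centers, indexing="ij")
    d2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2
    g = amplitude * np.exp(-LN5 * d2 / radius**2)
    if noise_sd:
        g = g + rng.normal(0.0, noise_sd, size=g.shape)
    return RateMap(g, np.ones((n_bins, n_bins), dtype=int), bin_size)


def synth_trace(alpha, k_phi, freq, phase_deg, times):
    phi = np.deg2rad(phase_deg)
    return alpha * np.exp(k_phi * (np.cos(2 * np.pi * freq * times - phi)
                                   - 1.0))


class TestRateMapRecovery:
    def test_shape_is_40_by_40(self):
        coder = init_model(4, 2, seed=0)
        pop = ECPopulation([])  # inputs unused: responses injected
        traj = Trajectory(np.arange(5) * 0.01,
                          np.full((5, 2), 0.5), np.zeros(5), np.zeros(5))
        maps = recover_rate_maps(coder, pop, traj,
                                 responses=np.ones((5, 2)))
        assert maps[0].grid.shape == (40, 40)

    def test_constant_response_fills_visited_bins(self):
        coder = init_model(4, 1, seed=0)
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 1, size=(500, 2))
        traj = Trajectory(np.arange(500) * 0.01, pos, np.zeros(500),
                          np.zeros(500))
        maps = recover_rate_maps(coder, ECPopulation([]), traj,
                                 responses=np.full((500, 1), 1.0))
        m = maps[0]
        assert np.all(m.grid[m.visited] == 1.0)
        assert np.all(m.grid[~m.visited] == 0.0)

    def test_bin_means_match_hand_computation(self):
        """Three samples falling in two bins: bin means are plain
        averages of the responses."""
        coder = init_model(4, 1, seed=0)
        pos = np.array([[0.011, 0.011], [0.016, 0.014], [0.9, 0.9]])
        traj = Trajectory(np.arange(3) * 0.01, pos, np.zeros(3),
                          np.zeros(3))
        responses = np.array([[1.0], [3.0], [5.0]])
        m = recover_rate_maps(coder, ECPopulation([]), traj,
                              responses=responses)[0]
        assert m.grid[0, 0] == pytest.approx(2.0)   # mean of 1 and 3
        assert m.grid[36, 36] == pytest.approx(5.0)
        assert m.occupancy[0, 0] == 2
        assert m.occupancy.sum() == 3

    def test_empty_trajectory_rejected(self):
        coder = init_model(4, 1, seed=0)
        traj = Trajectory(np.empty(0), np.empty((0, 2)), np.empty(0),
                          np.empty(0))
        with pytest.raises(ValueError):
            recover_rate_maps(coder, ECPopulation([]), traj)


class TestSpatialFit:
    def test_noiseless_self_consistency(self):
        m = bump_map(2.0, (0.5, 0.5), 0.10)
        f = fit_spatial_field(m)
        assert f.amplitude == pytest.approx(2.0, abs=1e-3)
        np.testing.assert_allclose(f.center, (0.5, 0.5), atol=1e-3)
        assert f.radius == pytest.approx(0.10, abs=1e-3)
        assert f.fit_error < 1e-6

    def test_all_zero_map_flagged_degenerate(self):
        m = RateMap(np.zeros((40, 40)), np.ones((40, 40), dtype=int),
                    0.025)
        f = fit_spatial_field(m)
        assert not f.converged
        assert f.amplitude == pytest.approx(0.0, abs=1e-9)

    def test_two_bump_map_has_large_error(self):
        a = bump_map(1.0, (0.25, 0.25), 0.08).grid
        b = bump_map(1.0, (0.75, 0.75), 0.08).grid
        m = RateMap(a + b, np.ones((40, 40), dtype=int), 0.025)
        f = fit_spatial_field(m)
        assert f.fit_error > 0.40
        sel, _ = select_place_cells([f])
        assert len(sel) == 0

    def test_too_few_visited_bins_rejected(self):
        occ = np.zeros((40, 40), dtype=int)
        occ[0, :5] = 1
        m = RateMap(np.zeros((40, 40)), occ, 0.025)
        with pytest.raises(ValueError):
            fit_spatial_field(m)

    def test_unvisited_bins_do_not_bias_fit(self):
        """Masking out a corner (unvisited) leaves the noiseless fit
        intact rather than dragging it toward imputed zeros."""
        m = bump_map(1.5, (0.3, 0.7), 0.09)
        m.occupancy[25:, :10] = 0
        m.grid[25:, :10] = 7.7  # garbage in unvisited bins is ignored
        f = fit_spatial_field(m)
        np.testing.assert_allclose(f.center, (0.3, 0.7), atol=1e-3)
        assert f.fit_error < 1e-6

    def test_parameter_recovery_under_noise(self, rng):
        """With 5% additive noise, median centre error is below half a
        bin and median radius error below 10% (100 synthetic fields)."""
        center_err, radius_err = [], []
        for _ in range(100):
            amp = rng.uniform(0.5, 3.0)
            ctr = rng.uniform(0.2, 0.8, size=2)
            rad = rng.uniform(0.06, 0.15)
            m = bump_map(amp, ctr, rad, noise_sd=0.05 * amp, rng=rng)
            f = fit_spatial_field(m)
            center_err.append(np.linalg.norm(f.center - ctr))
            radius_err.append(abs(f.radius - rad) / rad)
        assert np.median(center_err) < 0.0125
        assert np.median(radius_err) < 0.10


class TestSelection:
    def make_fit(self, center=(0.5, 0.5), radius=0.08, err=0.1):
        return SpatialFit(1.0, np.asarray(center, float), radius, err)

    def test_three_criteria(self):
        fits = [
            self.make_fit(radius=0.04),            # too small
            self.make_fit(center=(1.05, 0.5)),     # centre outside
            self.make_fit(err=0.39, radius=0.08),  # boundary accept
            self.make_fit(err=0.41),               # error too large
            None,                                  # unfittable map
        ]
        sel, inside = select_place_cells(fits)
        assert list(sel) == [2]
        assert list(inside) == [2]

    def test_fully_inside_subset(self):
        fits = [self.make_fit(center=(0.05, 0.5), radius=0.08),
                self.make_fit(center=(0.5, 0.5), radius=0.08)]
        sel, inside = select_place_cells(fits)
        assert list(sel) == [0, 1]
        assert list(inside) == [1]


class TestTemporalFit:
    times = np.arange(100) * 0.01

    def test_noiseless_self_consistency(self):
        """Recovers the example fit values alpha=2.68, k_phi=0.69,
        F=10 Hz, phi=177.77 deg to 1e-3."""
        trace = synth_trace(2.68, 0.69, 10.0, 177.77, self.times)
        f = fit_temporal_response(self.times, trace)
        assert f.valid
        assert f.amplitude == pytest.approx(2.68, abs=1e-3)
        assert f.k_phi == pytest.approx(0.69, abs=1e-3)
        assert f.freq == pytest.approx(10.0, abs=1e-3)
        assert f.phase == pytest.approx(177.77, abs=1e-3)
        assert f.fit_error < 1e-10

    def test_constant_trace_flagged_invalid(self):
        f = fit_temporal_response(self.times, np.full(100, 1.3))
        assert not f.valid
        assert f.k_phi == pytest.approx(0.0, abs=1e-6)

    def test_flat_zero_trace_flagged(self):
        f = fit_temporal_response(self.times, np.zeros(100))
        assert not f.valid

    def test_phase_wrap_equivalence(self):
        a = fit_temporal_response(self.times,
                                  synth_trace(1.0, 0.9, 10.0, 0.0,
                                              self.times))
        b = fit_temporal_response(self.times,
                                  synth_trace(1.0, 0.9, 10.0, 360.0,
                                              self.times))
        assert a.phase == pytest.approx(b.phase % 360.0, abs=1e-6)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            fit_temporal_response(np.arange(10) * 0.01, np.ones(10))

    def test_frequency_recovery_under_noise(self, rng):
        """F-hat within 2% of truth at 5% noise."""
        errs = []
        for _ in range(30):
            alpha = rng.uniform(0.5, 3.0)
            trace = synth_trace(alpha, rng.uniform(0.5, 1.2), 10.0,
                                rng.uniform(0, 360), self.times)
            trace = trace + rng.normal(0, 0.05 * alpha, size=100)
            f = fit_temporal_response(self.times, trace)
            errs.append(abs(f.freq - 10.0) / 10.0)
        assert np.median(errs) < 0.02


class TestPdcd:
    def test_straight_center_pass_endpoints(self):
        c, R = np.array([0.5, 0.5]), 0.1
        east = (1.0, 0.0)
        assert normalized_pdcd((0.4, 0.5), east, c, R) == pytest.approx(0.0)
        assert normalized_pdcd((0.5, 0.5), east, c, R) == pytest.approx(0.5)
        assert normalized_pdcd((0.6, 0.5), east, c, R) == pytest.approx(1.0)

    def test_off_center_chord_spans_unit_interval(self):
        c, R = np.array([0.5, 0.5]), 0.1
        east = (1.0, 0.0)
        rp = np.sqrt(R**2 - (R / 2) ** 2)
        y = 0.5 + R / 2
        assert normalized_pdcd((0.5 - rp, y), east, c, R) == pytest.approx(
            0.0, abs=1e-12)
        assert normalized_pdcd((0.5 + rp, y), east, c, R) == pytest.approx(
            1.0, abs=1e-12)

    def test_reversed_heading_mirrors(self, rng):
        c, R = np.array([0.5, 0.5]), 0.1
        for _ in range(20):
            r = c + rng.uniform(-0.07, 0.07, size=2)
            h = rng.normal(size=2)
            x = normalized_pdcd(r, h, c, R)
            y = normalized_pdcd(r, -h, c, R)
            assert x == pytest.approx(1.0 - y, abs=1e-12)

    def test_monotone_along_straight_segment(self):
        c, R = np.array([0.5, 0.5]), 0.1
        h = np.array([0.8, 0.6])
        start = c - 0.05 * h
        vals = [normalized_pdcd(start + f * 0.09 * h, h, c, R)
                for f in np.linspace(0, 1, 25)]
        assert np.all(np.diff(vals) > 0)

    def test_tangent_line_degenerate(self):
        """A running line at perpendicular offset >= R never enters the
        disc: the chord is degenerate."""
        with pytest.raises(DegenerateChordError):
            normalized_pdcd((0.5, 0.65), (1.0, 0.0), np.array([0.5, 0.5]),
                            0.1)


class TestPrecessionMeasurement:
    def test_synthetic_linear_precession(self, monkeypatch):
        """A cell whose firing phase falls linearly from 310 to 10 deg in
        pdcd gives entry ~310, exit ~10 and correlation -1."""
        fit = SpatialFit(1.0, np.array([0.5, 0.5]), 0.1, 0.0)
        times = np.arange(100) * 0.01

        def fake_trace(coder, population, r, heading, cell_index=None,
                       duration=1.0, dt=0.01, warmup=0.1):
            x = normalized_pdcd(r, heading, fit.center, fit.radius)
            phase = 310.0 - 300.0 * x
            return times, synth_trace(2.0, 0.8, 10.0, phase, times)

        monkeypatch.setattr(an, "response_trace_at", fake_trace)
        p = an.measure_precession(None, _DummyPop(), 0, fit, seed=3,
                                  straight=True)
        # first/last in-field samples sit one step inside the boundary
        assert p.entry_phase == pytest.approx(310.0, abs=6.0)
        assert p.exit_phase == pytest.approx(10.0, abs=6.0)
        assert p.correlation == pytest.approx(-1.0, abs=1e-3)
        assert not p.wrapped

    def test_constant_phase_flagged(self, monkeypatch):
        fit = SpatialFit(1.0, np.array([0.5, 0.5]), 0.1, 0.0)
        times = np.arange(100) * 0.01

        def fake_trace(coder, population, r, heading, cell_index=None,
                       duration=1.0, dt=0.01, warmup=0.1):
            return times, synth_trace(2.0, 0.8, 10.0, 123.0, times)

        monkeypatch.setattr(an, "response_trace_at", fake_trace)
        p = an.measure_precession(None, _DummyPop(), 0, fit, seed=3,
                                  straight=True)
        assert np.isnan(p.correlation)
        assert p.entry_phase == pytest.approx(123.0, abs=1e-3)


class _DummyPop:
    arena_size = 1.0
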