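"""Trace recording, detector filtering and sampling-volume voxelization."""

import math

import numpy as np
import pytest

from tissuemc._kernels import TERM_TOP
from tissuemc.dataset import builtin_dataset, enumerate_dataset
from tissuemc.detectors import FluenceGridSpec
from tissuemc.engine import EngineConfig, run
from tissuemc.trace import (
    DetectorFiberFilter,
    SamplingVolume,
    TraceBuffer,
    TraceSpec,
    compute_sv,
    filter_traces,
    simulate_sampling_volume,
)


def _probe_config(n_packets=20000, seed=5, capacity=1000):
    cfg = enumerate_dataset(builtin_dataset("sv"))[0]
    cfg.n_packets = n_packets
    cfg.seed = seed
    cfg.trace = TraceSpec(capacity)
    return cfg


@pytest.fixture(scope="module")
def probe_run():
    return run(_probe_config())


def _manual_buffer(points, weight, kind=TERM_TOP):
    """One-packet TraceBuffer through the given event positions."""
    points = np.asarray(points, dtype=np.float32)
    cap = len(points)
    ev = np.zeros((1, cap, 7), dtype=np.float32)
    ev[0, :, 0:3] = points
    ev[0, :, 6] = weight
    nev = np.array([cap], dtype=np.int64)
    term = np.zeros((1, 8))
    term[0, 0:3] = points[-1]
    term[0, 5] = -1.0
    term[0, 6] = weight
    term[0, 7] = kind
    return TraceBuffer(ev, nev, term, cap)


class TestTraceRecording:
    def test_weights_non_increasing_along_traces(self, probe_run):
        buf = probe_run.trace
        for ip in range(0, buf.n_packets, 97):
            n = buf.n_events[ip]
            w = buf.events[ip, :n, 6]
            assert np.all(np.diff(w) <= 1e-7)

    def test_events_bounded_by_capacity(self, probe_run):
        buf = probe_run.trace
        assert np.all(buf.n_events <= buf.capacity)

    def test_overflowing_packets_are_counted_and_flagged(self):
        r = run(_probe_config(n_packets=3000, seed=6, capacity=64))
        buf = r.trace
        assert buf.overflow_count > 0
        assert r.trace_dropped == buf.overflow_count

    def test_terminal_exit_directions_point_upward(self, probe_run):
        t = probe_run.trace.terminal
        top = t[:, 7] == TERM_TOP
        assert top.sum() > 0
        assert np.all(t[top, 5] < 0)


class TestFilterTraces:
    def test_whole_surface_detector_keeps_all_top_exits(self, probe_run):
        buf = probe_run.trace
        det = DetectorFiberFilter(center=(0, 0), core_radius=1.0, na=1.0,
                                  n_exit=1.0)
        sel = filter_traces(buf, det)
        assert sel.size == int(np.sum(buf.terminal[:, 7] == TERM_TOP))

    def test_zero_radius_detector_keeps_nothing(self, probe_run):
        det = DetectorFiberFilter(center=(0, 0), core_radius=0.0)
        assert filter_traces(probe_run.trace, det).size == 0

    def test_matches_brute_force_rescan(self, probe_run):
        buf = probe_run.trace
        det = DetectorFiberFilter(center=(500e-6, 0.0), core_radius=100e-6,
                                  na=0.22, n_exit=1.462)
        sel = set(filter_traces(buf, det).tolist())
        cos_min = det.cos_min
        expected = set()
        for ip in range(buf.n_packets):
            x, y, _z, _ux, _uy, uz, _w, kind = buf.terminal[ip]
            if kind != TERM_TOP:
                continue
            if (x - 500e-6) ** 2 + y**2 > (100e-6) ** 2:
                continue
            if abs(uz) < cos_min:
                continue
            expected.add(ip)
        assert sel == expected


class TestComputeSv:
    def test_straight_segment_hand_geometry(self):
        """A packet travelling straight down through voxels of height h
        deposits h·w per fully traversed voxel, clipped at the ends."""
        w = 0.25
        buf = _manual_buffer([[5e-5, 5e-5, 0.0], [5e-5, 5e-5, 9.5e-4]], w)
        grid = FluenceGridSpec((0, 0, 0), (1e-4, 1e-4, 1e-4), (1, 1, 10))
        sv = compute_sv(buf, np.array([0]), grid)
        expected = np.full(10, 1e-4 * w)
        expected[-1] = 0.5e-4 * w
        np.testing.assert_allclose(sv.values[0, 0], expected, rtol=1e-6)

    def test_oblique_segment_conserves_length(self):
        p0, p1 = [0.01e-3, 0.02e-3, 0.0], [0.93e-3, 0.41e-3, 0.77e-3]
        w = 0.6
        buf = _manual_buffer([p0, p1], w)
        grid = FluenceGridSpec((0, 0, 0), (1e-4, 1e-4, 1e-4), (10, 10, 10))
        sv = compute_sv(buf, np.array([0]), grid)
        seg = np.linalg.norm(np.subtract(p1, p0, dtype=float))
        # positions are stored float32; compare against the float32 segment
        a = np.asarray(p0, np.float32).astype(float)
        b = np.asarray(p1, np.float32).astype(float)
        seg32 = np.linalg.norm(b - a)
        assert sv.values.sum() == pytest.approx(seg32 * w, rel=1e-6)

    def test_empty_selection_gives_zero_volume(self, probe_run):
        grid = FluenceGridSpec((0, 0, 0), (1e-4,) * 3, (5, 5, 5))
        sv = compute_sv(probe_run.trace, np.array([], dtype=np.int64), grid)
        assert np.all(sv.values == 0)

    def test_total_matches_independent_clipping_oracle(self, probe_run):
        """SV sum equals Σ packets (in-grid path × terminal weight) where
        the oracle clips each segment analytically (no voxel walk)."""
        buf = probe_run.trace
        det = DetectorFiberFilter(center=(500e-6, 0.0), core_radius=100e-6,
                                  na=0.22, n_exit=1.462)
        sel = filter_traces(buf, det)
        assert sel.size > 0
        grid = FluenceGridSpec((-0.25e-3, -0.25e-3, 0.0), (2.5e-5,) * 3,
                               (40, 20, 32))
        sv = compute_sv(buf, sel, grid)
        lo = np.array(grid.origin)
        hi = lo + np.array(grid.voxel_size) * np.array(grid.shape)
        oracle = 0.0
        for ip in sel:
            w = buf.terminal[ip, 6]
            n = buf.n_events[ip]
            pts = buf.events[ip, :n, 0:3].astype(float)
            a, b = pts[:-1], pts[1:]
            d = b - a
            seg = np.linalg.norm(d, axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t0 = np.where(d != 0, (lo - a) / d, -np.inf)
                t1 = np.where(d != 0, (hi - a) / d, np.inf)
            tlo = np.minimum(t0, t1)
            thi = np.maximum(t0, t1)
            enter = np.max(tlo, axis=1)
            leave = np.min(thi, axis=1)
            # segments with a zero component outside the box contribute 0
            outside0 = np.any((d == 0) & ((a < lo) | (a >= hi)), axis=1)
            frac = np.clip(leave, 0, 1) - np.clip(enter, 0, 1)
            frac = np.where((frac > 0) & ~outside0, frac, 0.0)
            oracle += float(np.sum(frac * seg) * w)
        assert sv.values.sum() == pytest.approx(oracle, rel=1e-9)
        assert sv.values.sum() == pytest.approx(sv.total, rel=1e-12)

    def test_grid_coarsening_is_exact(self, probe_run):
        """Summing the SV over 2×-coarsened blocks equals computing it on
        the coarse grid directly."""
        buf = probe_run.trace
        det = DetectorFiberFilter(center=(500e-6, 0.0), core_radius=100e-6,
                                  na=0.22, n_exit=1.462)
        sel = filter_traces(buf, det)
        fine = FluenceGridSpec((-0.2e-3, -0.2e-3, 0.0), (2.5e-5,) * 3,
                               (32, 16, 32))
        coarse = FluenceGridSpec((-0.2e-3, -0.2e-3, 0.0), (5e-5,) * 3,
                                 (16, 8, 16))
        sv_f = compute_sv(buf, sel, fine)
        sv_c = compute_sv(buf, sel, coarse)
        pooled = sv_f.values.reshape(16, 2, 8, 2, 16, 2).sum(axis=(1, 3, 5))
        np.testing.assert_allclose(pooled, sv_c.values, rtol=1e-9,
                                   atol=1e-15 * sv_c.values.max())


@pytest.fixture(scope="module")
def probe_sv():
    cfg = _probe_config(n_packets=1, seed=0)
    cfg.trace = TraceSpec(1000)
    det = DetectorFiberFilter(center=(500e-6, 0.0), core_radius=100e-6,
                              na=0.22, n_exit=1.462)
    grid = FluenceGridSpec((-0.25e-3, -0.25e-3, 0.0), (2.5e-5,) * 3,
                           (40, 20, 32))
    return simulate_sampling_volume(cfg, det, grid, n_packets=150_000,
                                    seed=77, batch_size=15_000)


class TestProbeSamplingVolume:
    def test_mass_concentrates_between_the_fibers(self, probe_sv):
        """The banana-shaped path puts more SV mass in the half-space
        between source and detector fiber than outside it."""
        assert probe_sv.n_detected >= 10
        xc = -0.25e-3 + (np.arange(40) + 0.5) * 2.5e-5
        between = probe_sv.values[(xc > 0) & (xc < 500e-6)].sum()
        outside = probe_sv.values[(xc <= 0) | (xc >= 500e-6)].sum()
        assert between > outside

    def test_centroid_lies_between_the_fibers(self, probe_sv):
        xc = -0.25e-3 + (np.arange(40) + 0.5) * 2.5e-5
        mass_x = probe_sv.values.sum(axis=(1, 2))
        centroid = np.sum(xc * mass_x) / mass_x.sum()
        assert 0.0 < centroid < 500e-6

    def test_mirror_symmetry_about_the_fiber_axis(self, probe_sv):
        """y-averaged SV is symmetric about the source–detector plane
        within Monte Carlo noise."""
        vals = probe_sv.values
        upper = vals[:, 10:, :].sum()
        lower = vals[:, :10, :].sum()
        assert abs(upper - lower) / (upper + lower) < 0.35

    def test_normalized_view_scales_with_launch_count(self, probe_sv):
        dx, dy, dz = probe_sv.spec.voxel_size
        expected = probe_sv.values / (probe_sv.n_launched * dx * dy * dz)
        np.testing.assert_allclose(probe_sv.normalized(), expected)
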