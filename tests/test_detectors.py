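"""Surface detectors, normalizations and the fiber-integration utility."""

import math

import numpy as np
import pytest

from tissuemc.dataset import one_layer_stack
from tissuemc.detectors import (
    CartesianAccumulator,
    CartesianXDetector,
    FiberArrayAccumulator,
    FiberArrayDetectorSpec,
    FluenceGrid,
    FluenceGridSpec,
    RadialAccumulator,
    RadialDetector,
    SimResult,
    integrate_radial_to_fiber,
    linear_edges,
    log_edges,
    na_to_cos_min,
    normalize_fluence,
    normalize_radial,
    score_exit,
    symmetric_log_edges,
)
from tissuemc.engine import DetectorSet, EngineConfig, run_layered
from tissuemc.geometry import Pencil


class TestEdges:
    def test_log_edges_start_at_zero(self):
        e = log_edges(150e-3, 4000)
        assert e[0] == 0.0
        assert e.size == 4001
        assert e[-1] == pytest.approx(150e-3)
        assert np.all(np.diff(e) > 0)

    def test_symmetric_log_edges(self):
        e = symmetric_log_edges(150e-3, 8000)
        assert e.size == 8001
        np.testing.assert_allclose(e, -e[::-1], atol=0)

    def test_na_to_cos_min(self):
        assert na_to_cos_min(1.0) == 0.0
        assert na_to_cos_min(0.22) == pytest.approx(math.sqrt(1 - 0.22**2))
        assert na_to_cos_min(0.22, 1.462) == pytest.approx(
            math.sqrt(1 - (0.22 / 1.462) ** 2))


class TestScoreExit:
    def test_full_aperture_scores_everything(self):
        acc = RadialAccumulator(RadialDetector.from_na(
            linear_edges(5e-3, 50), 1.0), n_reference=10)
        for ang in np.linspace(0.01, math.pi / 2 - 0.01, 25):
            d = np.array([math.sin(ang), 0.0, -math.cos(ang)])
            assert score_exit(acc, (1e-3, 0, 0), d, 0.1)
        assert acc.discarded == 0.0

    def test_acceptance_cone_rejects_oblique_exit(self):
        acc = RadialAccumulator(
            RadialDetector(linear_edges(5e-3, 50),
                           cos_min=math.cos(math.radians(10))), 10)
        d15 = np.array([math.sin(math.radians(15)), 0.0,
                        -math.cos(math.radians(15))])
        assert not score_exit(acc, (1e-3, 0, 0), d15, 0.2)
        assert acc.discarded == pytest.approx(0.2)

    def test_half_open_bin_assignment(self):
        edges = linear_edges(5e-3, 50)
        acc = RadialAccumulator(RadialDetector(edges), 10)
        down = np.array([0.0, 0.0, -1.0])
        score_exit(acc, (0.9 * edges[1], 0, 0), down, 1.0)
        assert acc.raw[0] == 1.0
        score_exit(acc, (edges[1], 0, 0), down, 1.0)
        assert acc.raw[1] == 1.0

    def test_overflow_is_tracked(self):
        acc = RadialAccumulator(RadialDetector(linear_edges(1e-3, 10)), 10)
        assert not score_exit(acc, (2e-3, 0, 0), np.array([0, 0, -1.0]), 0.5)
        assert acc.overflow == 0.5

    def test_tilted_cartesian_axis(self):
        det = CartesianXDetector(np.linspace(-5e-3, 5e-3, 11), tilt_deg=20.0,
                                 acceptance_deg=10.0)
        acc = CartesianAccumulator(det, 10)
        t = math.radians(20.0)
        along = np.array([math.sin(t), 0.0, -math.cos(t)])
        assert score_exit(acc, (0, 0, 0), along, 1.0)
        # perpendicular exit is 20 degrees off the tilted axis: rejected
        assert not score_exit(acc, (0, 0, 0), np.array([0, 0, -1.0]), 1.0)

    def test_fiber_array_attribution(self):
        spec = FiberArrayDetectorSpec(np.array([[0.0, 0.0], [1e-3, 0.0]]),
                                      100e-6, na=0.22)
        acc = FiberArrayAccumulator(spec, 10)
        assert score_exit(acc, (1e-3 + 50e-6, 0, 0),
                          np.array([0, 0, -1.0]), 0.4)
        assert acc.raw[1] == pytest.approx(0.4)
        # outside the NA cone: discarded
        ang = math.asin(0.5)
        assert not score_exit(acc, (0, 0, 0),
                              np.array([math.sin(ang), 0, -math.cos(ang)]),
                              0.3)
        assert acc.discarded == pytest.approx(0.3)


class TestNormalization:
    def test_radial_single_ring_inverse_area(self):
        edges = linear_edges(1e-3, 4)
        acc = RadialAccumulator(RadialDetector(edges), n_reference=1000)
        acc.raw[2] = 1000.0
        area = math.pi * (edges[3] ** 2 - edges[2] ** 2)
        values = normalize_radial(acc)
        assert values[2] == pytest.approx(1.0 / area)
        assert values[0] == 0.0

    def test_scaling_invariance(self):
        edges = linear_edges(1e-3, 4)
        a = RadialAccumulator(RadialDetector(edges), 100)
        b = RadialAccumulator(RadialDetector(edges), 200)
        a.raw[:] = [1, 2, 3, 4]
        b.raw[:] = [2, 4, 6, 8]
        np.testing.assert_allclose(normalize_radial(a), normalize_radial(b))

    def test_normalization_inverse_recovers_total(self, rng):
        edges = log_edges(5e-3, 30)
        acc = RadialAccumulator(RadialDetector(edges), 1234)
        acc.raw[:] = rng.random(30)
        values = normalize_radial(acc)
        areas = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        assert np.sum(values * areas) == pytest.approx(
            acc.raw.sum() / 1234, rel=1e-12)

    def test_requires_positive_reference(self):
        acc = RadialAccumulator(RadialDetector(linear_edges(1e-3, 4)), 0)
        with pytest.raises(ValueError):
            normalize_radial(acc)

    def test_fluence_single_voxel_inverse_volume(self):
        spec = FluenceGridSpec((0, 0, 0), (1e-4, 1e-4, 2e-4), (3, 3, 3))
        grid = FluenceGrid(spec, n_reference=500)
        grid.raw[1, 1, 1] = 500.0
        v = normalize_fluence(grid)
        assert v[1, 1, 1] == pytest.approx(1.0 / (1e-4 * 1e-4 * 2e-4))

    def test_fluence_mode_divides_by_mua_and_masks_zero(self):
        spec = FluenceGridSpec((0, 0, 0), (1e-4,) * 3, (2, 1, 1),
                               mode="fluence")
        grid = FluenceGrid(spec, n_reference=10)
        grid.raw[:, 0, 0] = [10.0, 10.0]
        mua = np.array([[[100.0]], [[0.0]]])
        v = normalize_fluence(grid, mua)
        # dep = raw/(N·V) = 1e12 1/m³, fluence = dep/μa = 1e10 1/m²
        assert v[0, 0, 0] == pytest.approx(1e10)
        assert np.isnan(v[1, 0, 0])


class TestEngineBookkeeping:
    def test_scored_plus_discarded_plus_overflow_equals_escaped(self):
        """Radial bins + acceptance-discarded + overflow account for every
        escaping packet to 1e-9 relative."""
        det = DetectorSet(
            top=RadialDetector(linear_edges(0.5e-3, 20),
                               cos_min=math.cos(math.radians(30))),
            bottom=RadialDetector(linear_edges(0.5e-3, 20),
                                  cos_min=math.cos(math.radians(30))),
        )
        cfg = EngineConfig(one_layer_stack(2.5, 30.0, 0.9, 1e-3), Pencil(),
                           5 * 10**4, seed=55, detectors=det)
        r = run_layered(cfg)
        top_total = r.top.raw.sum() + r.top.discarded + r.top.overflow
        assert top_total == pytest.approx(r.reflectance, rel=1e-9)
        bot_total = r.bottom.raw.sum() + r.bottom.discarded + r.bottom.overflow
        assert bot_total == pytest.approx(r.transmittance, rel=1e-9)
        assert r.top.discarded > 0 and r.top.overflow > 0

    def test_total_deposit_equals_absorbed_fraction(self):
        """With the grid covering the whole sample, the deposited weight
        equals the energy-balance absorbed fraction to 1e-12."""
        cfg = EngineConfig(
            one_layer_stack(2.5, 30.0, 0.9, 1e-3), Pencil(), 2 * 10**4,
            seed=56,
            fluence=FluenceGridSpec((-0.1, -0.1, 0.0), (0.2, 0.2, 1e-4),
                                    (1, 1, 10)),
        )
        r = run_layered(cfg)
        assert r.fluence.raw.sum() / r.n_packets == pytest.approx(
            r.absorbed_fraction, rel=1e-12)

    def test_energy_deposition_decays_beyond_diffuse_peak(self):
        """The z profile of deposited energy (μa=2.5 cm⁻¹, μs′=30 cm⁻¹,
        g=0.9) is nonnegative and decays monotonically past the peak."""
        cfg = EngineConfig(
            one_layer_stack(2.5, 30.0, 0.9, 5e-3), Pencil(), 2 * 10**5,
            seed=57,
            fluence=FluenceGridSpec((-0.1, -0.1, 0.0), (0.2, 0.2, 0.25e-3),
                                    (1, 1, 20)),
        )
        r = run_layered(cfg)
        profile = r.fluence.raw[0, 0, :]
        assert np.all(profile >= 0)
        peak = int(np.argmax(profile))
        assert peak < 4
        assert np.all(np.diff(profile[peak:]) < 0)


class TestFiberIntegration:
    def test_uniform_profile_times_core_area(self):
        edges = linear_edges(5e-3, 500)
        val = integrate_radial_to_fiber(np.full(500, 3.0), edges,
                                        sds=1e-3, core_radius=100e-6)
        assert val == pytest.approx(3.0 * math.pi * (100e-6) ** 2, rel=1e-12)

    def test_centred_disc_reduces_to_inner_rings(self):
        edges = linear_edges(5e-3, 500)
        srr = np.zeros(500)
        srr[:20] = 2.0
        # disc centred on the axis covering exactly the first 10 rings
        a = edges[10]
        val = integrate_radial_to_fiber(srr, edges, sds=0.0, core_radius=a)
        assert val == pytest.approx(2.0 * math.pi * a**2, rel=1e-9)

    def test_matches_monte_carlo_area_integration(self, rng):
        edges = linear_edges(5e-3, 120)
        srr = rng.random(120) * 1e3
        sds, a = 1.3e-3, 300e-6
        exact = integrate_radial_to_fiber(srr, edges, sds, a)
        n = 10**6
        rr = a * np.sqrt(rng.random(n))
        th = 2 * np.pi * rng.random(n)
        radius = np.hypot(sds + rr * np.cos(th), rr * np.sin(th))
        idx = np.clip(np.searchsorted(edges, radius, side="right") - 1,
                      0, 119)
        mc = srr[idx].mean() * math.pi * a**2
        assert mc == pytest.approx(exact, rel=1e-3)

    def test_footprint_beyond_edges_rejected(self):
        edges = linear_edges(1e-3, 10)
        with pytest.raises(ValueError, match="beyond"):
            integrate_radial_to_fiber(np.ones(10), edges, 0.95e-3, 100e-6)


class TestSimResultIO:
    def test_npz_round_trip_scalars(self, tmp_path):
        cfg = EngineConfig(one_layer_stack(2.5, 30.0, 0.9, 1e-3), Pencil(),
                           5000, seed=58,
                           detectors=DetectorSet(
                               top=RadialDetector(linear_edges(5e-3, 50))))
        r = run_layered(cfg)
        p = tmp_path / "result.npz"
        r.save_npz(p)
        scalars = SimResult.load_scalars(p)
        assert scalars["reflectance"] == r.reflectance
        assert scalars["n_packets"] == 5000

    def test_hdf5_round_trip_scalars(self, tmp_path):
        cfg = EngineConfig(one_layer_stack(2.5, 30.0, 0.9, 1e-3), Pencil(),
                           5000, seed=59)
        r = run_layered(cfg)
        p = tmp_path / "result.h5"
        r.save_hdf5(p)
        scalars = SimResult.load_scalars(p)
        assert scalars["transmittance"] == r.transmittance
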