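"""Full transport runs: conservation laws, limits, cross-engine and
cross-method equivalences, determinism."""

import copy
import math

import numpy as np
import pytest

from tissuemc.dataset import (
    fixture_configs,
    layered_to_voxel,
    linear_array_layout,
    one_layer_stack,
    two_layer_benchmark,
)
from tissuemc.engine import EngineConfig, Roulette, run, run_layered, run_voxel
from tissuemc.geometry import (
    FiberSource,
    IsotropicPoint,
    Layer,
    LayerStack,
    Pencil,
    VoxelMaterial,
    VoxelVolume,
)
from tissuemc.phase import HenyeyGreenstein

HG9 = HenyeyGreenstein(0.9)


def _sigma_diff(a, b, what="R"):
    if what == "R":
        return math.hypot(a.reflectance_stderr(), b.reflectance_stderr())
    return math.hypot(a.transmittance_stderr(), b.transmittance_stderr())


class TestLayeredLimits:
    def test_beer_lambert_ballistic_transmission(self):
        """μs=0, matched indices, μa·d=1: T = e⁻¹."""
        stack = LayerStack.from_layers(
            [Layer(1000.0, 0.0, 1.0, 1e-3, None)], 1.0, 1.0)
        r = run_layered(EngineConfig(stack, Pencil(), 10**5, seed=4))
        sigma = math.sqrt(math.exp(-1) * (1 - math.exp(-1)) / 10**5)
        assert abs(r.total_transmittance - math.exp(-1)) < 3 * sigma
        assert r.total_reflectance == 0.0

    def test_nonabsorbing_slab_conserves_weight(self):
        """μa=0, μs>0, matched indices: every packet escapes with its full
        weight, so R + T = 1 exactly."""
        stack = LayerStack.from_layers(
            [Layer(0.0, 500.0, 1.0, 2e-3, HG9)], 1.0, 1.0)
        r = run_layered(EngineConfig(stack, Pencil(), 2 * 10**4, seed=5))
        assert r.total_reflectance + r.total_transmittance == pytest.approx(
            1.0, abs=1e-12)
        assert r.absorbed == 0.0

    def test_layer_splitting_invariance(self):
        """Two identical stacked layers behave as one merged layer."""
        merged = LayerStack.from_layers(
            [Layer(250.0, 3000.0, 1.337, 1e-3, HG9)], 1.0, 1.337)
        split = LayerStack.from_layers(
            [Layer(250.0, 3000.0, 1.337, 0.5e-3, HG9),
             Layer(250.0, 3000.0, 1.337, 0.5e-3, HG9)], 1.0, 1.337)
        n = 3 * 10**5
        a = run_layered(EngineConfig(merged, Pencil(), n, seed=6))
        b = run_layered(EngineConfig(split, Pencil(), n, seed=7))
        assert abs(a.total_reflectance - b.total_reflectance) < \
            3 * _sigma_diff(a, b, "R")
        assert abs(a.total_transmittance - b.total_transmittance) < \
            3 * _sigma_diff(a, b, "T")

    def test_isotropic_source_inside_nonabsorbing_medium(self):
        stack = LayerStack.from_layers(
            [Layer(0.0, 2000.0, 1.0, 1e-3, HG9)], 1.0, 1.0)
        cfg = EngineConfig(stack, IsotropicPoint((0, 0, 0.5e-3)), 10**4,
                           seed=8)
        r = run_layered(cfg)
        assert r.specular == 0.0
        assert r.total_reflectance + r.total_transmittance == pytest.approx(
            1.0, abs=1e-12)


class TestEnergyBalance:
    @pytest.mark.parametrize("name", ["two-layer-pencil", "one-layer-gaussian",
                                      "semi-infinite-fiber",
                                      "six-around-one-probe",
                                      "voxel-two-layer-aw",
                                      "voxel-skin-vessel-mbl"])
    def test_balance_with_roulette_within_5_sigma(self, name):
        cfg = fixture_configs(10**5)[name]
        r = run(cfg)
        # the residual is the net of roulette kills against survivor gains,
        # zero-mean with a variance bounded through the killed total
        sigma = r.roulette_residual_sigma(cfg.roulette.threshold,
                                          cfg.roulette.m)
        assert abs(r.energy_balance_residual()) < 5 * sigma + 1e-9

    @pytest.mark.parametrize("name", ["two-layer-pencil", "voxel-two-layer-aw",
                                      "voxel-skin-vessel-mbl"])
    def test_balance_exact_with_roulette_disabled(self, name):
        cfg = fixture_configs(2 * 10**4)[name]
        cfg.roulette = Roulette(enabled=False)
        r = run(cfg)
        assert abs(r.energy_balance_residual()) < 1e-9


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = fixture_configs(2 * 10**4)["one-layer-gaussian"]
        a = run(cfg)
        b = run(copy.copy(cfg))
        assert a.reflectance == b.reflectance
        assert a.transmittance == b.transmittance
        np.testing.assert_array_equal(a.top.raw, b.top.raw)
        np.testing.assert_array_equal(a.bottom.raw, b.bottom.raw)

    def test_different_seeds_differ(self):
        cfg = fixture_configs(2 * 10**4)["one-layer-gaussian"]
        a = run(cfg)
        cfg2 = copy.copy(cfg)
        cfg2.seed = cfg.seed + 1
        b = run(cfg2)
        assert a.reflectance != b.reflectance


class TestVoxelEngine:
    def test_homogeneous_volume_matches_single_layer(self):
        stack = one_layer_stack(2.5, 30.0, 0.9, 1e-3)
        vol = layered_to_voxel(stack, 50e-6)
        n = 2 * 10**5
        a = run_layered(EngineConfig(stack, Pencil(), n, seed=21,
                                     boundary_mode="split"))
        b = run_voxel(EngineConfig(vol, Pencil(), n, seed=22,
                                   boundary_mode="split"))
        assert abs(a.total_reflectance - b.total_reflectance) < \
            3 * _sigma_diff(a, b, "R")
        assert abs(a.total_transmittance - b.total_transmittance) < \
            3 * _sigma_diff(a, b, "T")

    def test_stepping_methods_agree_on_total_deposition(self):
        """AW, AR and MBL are equivalent estimators of deposited energy."""
        stack = one_layer_stack(5.0, 20.0, 0.8, 1e-3)
        vol = layered_to_voxel(stack, 50e-6)
        n = 10**5
        results = {}
        for i, stepping in enumerate(("aw", "ar", "mbl")):
            cfg = EngineConfig(vol, Pencil(), n, seed=30 + i,
                               stepping=stepping)
            results[stepping] = run_voxel(cfg)
        a_aw = results["aw"].absorbed_fraction
        for other in ("ar", "mbl"):
            a_o = results[other].absorbed_fraction
            # AR deposits full packet weights: near-binomial variance bounds
            # the difference for all three estimators
            sigma = 2 * math.sqrt(a_aw * (1 - a_aw) / n)
            assert abs(a_aw - a_o) < 3 * sigma

    def test_empty_volume_is_ballistic(self):
        labels = np.zeros((3, 3, 10), dtype=np.int32)
        vol = VoxelVolume(labels, (1e-3, 1e-3, 1e-4),
                          {0: VoxelMaterial(0.0, 0.0, 1.0, None)},
                          n_above=1.0, n_below=1.0)
        r = run_voxel(EngineConfig(vol, Pencil(), 10**4, seed=33))
        assert r.total_transmittance == 1.0
        assert r.total_reflectance == 0.0

    def test_interior_index_mismatch_reflects(self):
        # two z-slabs with an index step: some packets return via Fresnel
        labels = np.zeros((1, 1, 20), dtype=np.int32)
        labels[:, :, 10:] = 1
        vol = VoxelVolume(labels, (2.0, 2.0, 1e-4),
                          {0: VoxelMaterial(0.0, 0.0, 1.0, None),
                           1: VoxelMaterial(0.0, 0.0, 1.5, None)},
                          n_above=1.0, n_below=1.5)
        r = run_voxel(EngineConfig(vol, Pencil(), 10**5, seed=34))
        expected_r = ((1.0 - 1.5) / (2.5)) ** 2
        sigma = math.sqrt(expected_r * (1 - expected_r) / 10**5)
        assert abs(r.total_reflectance - expected_r) < 3 * sigma
        assert r.total_reflectance + r.total_transmittance == pytest.approx(
            1.0, abs=1e-12)


class TestFiberDetectors:
    def test_six_around_one_symmetry(self):
        """A centred source makes the six surrounding fibers equivalent."""
        cfg = fixture_configs(6 * 10**5)["six-around-one-probe"]
        r = run(cfg)
        outer = r.fibers.raw[1:]
        mean = outer.mean()
        # ~600 detected packets per fiber: 4% relative counting noise
        assert np.all(np.abs(outer - mean) < 0.15 * mean)

    def test_linear_array_snr_decreases_with_separation(self):
        """Distant fibers need more packets for matched SNR: at fixed N the
        collected signal (and with it the counting-limited SNR) decreases
        monotonically with source-detector separation."""
        reps = []
        for k in range(8):
            stack = one_layer_stack(2.5, 30.0, 0.9, math.inf)
            cfg = EngineConfig(
                stack, FiberSource(200e-6, 220e-6, 0.22, 1.462),
                25_000, seed=40 + k, surface=linear_array_layout(6),
            )
            reps.append(run(cfg).fibers.raw[1:])
        reps = np.array(reps)
        signal = reps.mean(axis=0)
        assert np.all(np.diff(signal) < 0), f"signal not monotone: {signal}"
        snr = signal / (reps.std(axis=0) + 1e-30)
        # endpoint comparison is robust to the noisy 8-rep std estimates
        assert snr[-1] < snr[0]
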