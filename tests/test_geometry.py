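"""Geometry, sources, launch and surface interaction."""

import math

import numpy as np
import pytest

from tissuemc.geometry import (
    BoundingMedium,
    FiberProbeLayout,
    FiberSource,
    GaussianBeam,
    IsotropicPoint,
    Layer,
    LayerStack,
    Pencil,
    PhotonPacket,
    UniformBeam,
    VoxelMaterial,
    VoxelVolume,
    launch,
    linear_array_layout,
    locate_layer,
    six_around_one_layout,
    surface_interact,
    voxel_at,
)
from tissuemc.phase import HenyeyGreenstein

HG9 = HenyeyGreenstein(0.9)


def two_layer_stack():
    return LayerStack.from_layers(
        [Layer(250.0, 3000.0, 1.337, 100e-6, HG9),
         Layer(50.0, 2000.0, 1.337, 1e-3, HG9)],
        n_above=1.0, n_below=1.337,
    )


class TestLayerStack:
    def test_locate_layer_half_open_convention(self):
        stack = two_layer_stack()
        assert locate_layer(stack, 50e-6) == 1
        assert locate_layer(stack, 100e-6) == 2  # boundary belongs deeper
        assert locate_layer(stack, 1.2e-3) == 3  # bottom bounding medium
        assert locate_layer(stack, -1e-6) == 0

    def test_infinite_layer_owns_all_depths(self):
        stack = LayerStack.from_layers(
            [Layer(10.0, 100.0, 1.4, math.inf, HG9)], 1.0, 1.0)
        assert locate_layer(stack, 5.0) == 1

    def test_stack_validation(self):
        with pytest.raises(ValueError):
            LayerStack([BoundingMedium(1.0), BoundingMedium(1.0)])
        with pytest.raises(TypeError):
            LayerStack([BoundingMedium(1.0), BoundingMedium(1.0),
                        BoundingMedium(1.0)])
        with pytest.raises(ValueError):
            # infinite layer not last
            LayerStack.from_layers(
                [Layer(1.0, 0.0, 1.0, math.inf, None),
                 Layer(1.0, 0.0, 1.0, 1e-3, None)], 1.0, 1.0)
        with pytest.raises(ValueError):
            Layer(1.0, 100.0, 1.4, 1e-3, None)  # scattering needs a pf


class TestVoxelVolume:
    def _volume(self):
        labels = np.zeros((4, 5, 6), dtype=np.int32)
        labels[2:, :, :] = 1
        mats = {0: VoxelMaterial(10.0, 0.0, 1.4, None),
                1: VoxelMaterial(20.0, 0.0, 1.4, None)}
        return VoxelVolume(labels, (1e-4, 1e-4, 1e-4), mats,
                           origin=(0.0, 0.0, 0.0))

    def test_corner_belongs_to_minimal_voxel(self):
        vol = self._volume()
        ijk, mat = voxel_at(vol, (0.0, 0.0, 0.0))
        assert ijk == (0, 0, 0)
        ijk, _ = voxel_at(vol, (2e-4, 1e-4, 3e-4))
        assert ijk == (2, 1, 3)

    def test_outside_returns_escape_signal(self):
        vol = self._volume()
        assert voxel_at(vol, (-1e-6, 0, 0)) is None
        assert voxel_at(vol, (4e-4, 0, 0)) is None  # half-open positive face

    def test_matches_brute_force_scan(self, rng):
        vol = self._volume()
        nx, ny, nz = vol.shape
        for _ in range(200):
            p = rng.random(3) * np.array([4e-4, 5e-4, 6e-4])
            ijk, _ = voxel_at(vol, p)
            found = None
            for i in range(nx):
                for j in range(ny):
                    for k in range(nz):
                        lo = np.array([i, j, k]) * 1e-4
                        hi = lo + 1e-4
                        if np.all(p >= lo) and np.all(p < hi):
                            found = (i, j, k)
            assert ijk == found

    def test_missing_material_rejected(self):
        labels = np.ones((2, 2, 2), dtype=np.int32)
        with pytest.raises(ValueError, match="no material"):
            VoxelVolume(labels, 1e-4, {0: VoxelMaterial(1, 0, 1.4, None)})


class TestLaunch:
    def test_pencil_matched_index_carries_full_weight(self, rng):
        stack = LayerStack.from_layers(
            [Layer(100.0, 1000.0, 1.0, 1e-3, HG9)], 1.0, 1.0)
        packet, rsp = launch(Pencil(), stack, rng)
        assert packet.weight == 1.0
        assert rsp == 0.0
        np.testing.assert_allclose(packet.direction, [0, 0, 1])

    def test_pencil_specular_weight_for_mismatch(self, rng):
        stack = LayerStack.from_layers(
            [Layer(100.0, 1000.0, 1.4, 1e-3, HG9)], 1.0, 1.0)
        packet, rsp = launch(Pencil(), stack, rng)
        assert rsp == pytest.approx(0.02778, abs=1e-5)
        assert packet.weight == pytest.approx(1 - rsp)

    def test_gaussian_beam_radius_spread(self, rng):
        """Sample std of the launch x offset equals FWHM/2.3548."""
        stack = two_layer_stack()
        src = GaussianBeam(100e-6)
        xs = np.array([launch(src, stack, rng)[0].position[0]
                       for _ in range(30000)])
        assert xs.std() == pytest.approx(100e-6 / 2.3548, rel=0.02)

    def test_launch_invariants(self, rng):
        stack = two_layer_stack()
        sources = [Pencil(), GaussianBeam(50e-6), UniformBeam(200e-6),
                   IsotropicPoint((0, 0, 50e-6)),
                   FiberSource(200e-6, 220e-6, 0.22, 1.462)]
        for src in sources:
            for _ in range(200):
                packet, rsp = launch(src, stack, rng)
                assert packet.weight <= 1.0 + 1e-12
                assert abs(np.linalg.norm(packet.direction) - 1.0) < 1e-9
                assert 0.0 <= rsp <= 1.0

    def test_fiber_directions_inside_refracted_cone(self, rng):
        stack = two_layer_stack()
        src = FiberSource(200e-6, 220e-6, 0.22, 1.462)
        n_sample = stack.layers[0].n
        for _ in range(500):
            packet, _ = launch(src, stack, rng)
            sin_in_sample = math.hypot(packet.direction[0],
                                       packet.direction[1])
            assert sin_in_sample <= 0.22 / n_sample + 1e-9

    def test_fiber_positions_inside_core(self, rng):
        stack = two_layer_stack()
        src = FiberSource(200e-6, 220e-6, 0.22, 1.462, position=(1e-3, 0))
        for _ in range(200):
            packet, _ = launch(src, stack, rng)
            r = math.hypot(packet.position[0] - 1e-3, packet.position[1])
            assert r <= 100e-6 + 1e-12


class TestSurfaceLayouts:
    def test_six_around_one_tight_packing(self):
        lay = six_around_one_layout(cladding_diameter=220e-6)
        d = np.linalg.norm(lay.fiber_positions[1:] - lay.fiber_positions[0],
                           axis=1)
        np.testing.assert_allclose(d, 220e-6, rtol=1e-12)

    def test_linear_array_tight_packing(self):
        lay = linear_array_layout(6, cladding_diameter=220e-6)
        gaps = np.diff(lay.fiber_positions[:, 0])
        np.testing.assert_allclose(gaps, 220e-6, rtol=1e-12)

    def test_overlapping_fibers_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            FiberProbeLayout(np.array([[0, 0], [1e-4, 0]]), 100e-6, 110e-6,
                             0.22, 1.462, 1e-3)

    def test_housing_reflection_scales_weight(self, rng):
        lay = six_around_one_layout(tip_radius=2e-3, reflectivity=0.6)
        packet = PhotonPacket(np.array([1.5e-3, 0.0, 0.0]),
                              np.array([0.0, 0.0, -1.0]), weight=0.5)
        packet, outcome = surface_interact(lay, packet, rng, n_tissue=1.337)
        assert outcome == "reflected"
        assert packet.weight == pytest.approx(0.3)
        assert packet.direction[2] == 1.0  # specular flip

    def test_zero_reflectivity_terminates(self, rng):
        lay = six_around_one_layout(tip_radius=2e-3, reflectivity=0.0)
        packet = PhotonPacket(np.array([1.5e-3, 0.0, 0.0]),
                              np.array([0.0, 0.0, -1.0]), weight=0.5)
        packet, outcome = surface_interact(lay, packet, rng, n_tissue=1.337)
        assert outcome == "terminated"
        assert not packet.alive

    def test_exit_through_core_is_attributed_to_fiber(self, rng):
        lay = six_around_one_layout(tip_radius=2e-3)
        packet = PhotonPacket(np.array([0.0, 0.0, 0.0]),
                              np.array([0.0, 0.0, -1.0]), weight=1.0)
        packet, outcome = surface_interact(lay, packet, rng, n_tissue=1.462)
        # matched index: never reflected
        assert outcome == "fiber:0"

    def test_trivial_layout_matches_plain_boundary(self):
        """A probe with zero tip radius and no nearby fiber behaves exactly
        like the bare sample–air boundary for identical random streams."""
        lay = FiberProbeLayout(np.array([[1.0, 1.0]]), 100e-6, 110e-6, 0.22,
                               1.462, tip_radius=0.0, n_outside=1.0)
        base = np.random.default_rng(7)
        for _ in range(1000):
            ux, uy = base.normal(size=2) * 0.4
            uz = -math.sqrt(max(1e-6, 1 - ux * ux - uy * uy))
            norm = math.hypot(math.hypot(ux, uy), uz)
            d = np.array([ux / norm, uy / norm, uz / norm])
            seed = int(base.integers(2**31))
            pos = np.array([2e-3, 1e-3, 0.0])  # outside tip, away from fiber
            p1 = PhotonPacket(pos.copy(), d.copy(), weight=0.8)
            p2 = PhotonPacket(pos.copy(), d.copy(), weight=0.8)
            r1 = surface_interact(lay, p1, np.random.default_rng(seed), 1.337)
            r2 = surface_interact(None, p2, np.random.default_rng(seed), 1.337)
            assert r1[1] == r2[1]
            np.testing.assert_allclose(r1[0].direction, r2[0].direction,
                                       atol=1e-12)

    def test_lambertian_option_reflects_downward(self, rng):
        lay = six_around_one_layout(tip_radius=2e-3)
        lay.reflection = "lambertian"
        packet = PhotonPacket(np.array([1.5e-3, 0.0, 0.0]),
                              np.array([0.0, 0.0, -1.0]), weight=1.0)
        packet, outcome = surface_interact(lay, packet, rng, 1.337)
        assert outcome == "reflected"
        assert packet.direction[2] > 0
        assert abs(np.linalg.norm(packet.direction) - 1) < 1e-9


class TestPhotonPacket:
    def test_direction_must_be_unit(self):
        with pytest.raises(ValueError):
            PhotonPacket(np.zeros(3), np.array([0.0, 0.0, 0.5]))

    def test_weight_nonnegative(self):
        with pytest.raises(ValueError):
            PhotonPacket(np.zeros(3), np.array([0.0, 0.0, 1.0]), weight=-0.1)
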