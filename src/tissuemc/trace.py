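"""Photon-packet traces and sampling-volume computation.

A trace records position, direction and weight at every launch, scattering,
refraction/reflection and terminal event of a packet, up to a fixed
capacity (1000 events by default; packets that exceed it are excluded from
sampling volumes and counted).  Filtered traces — packets whose terminal
state satisfies a detector-fiber test — are voxelized into a sampling
volume: each voxel accumulates the path length traversed inside it times
the packet's terminal weight, a 3D map of where detected light travelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kernels import TERM_TOP, sv_accumulate
from .detectors import FluenceGridSpec, na_to_cos_min

__all__ = [
    "TraceSpec",
    "TraceBuffer",
    "DetectorFiberFilter",
    "SamplingVolume",
    "filter_traces",
    "compute_sv",
    "simulate_sampling_volume",
]

DEFAULT_TRACE_CAPACITY = 1000


@dataclass
class TraceSpec:
    """Trace request: maximum number of recorded events per packet."""

    capacity: int = DEFAULT_TRACE_CAPACITY

    def __post_init__(self):
        if self.capacity < 2:
            raise ValueError("trace capacity must be >= 2")


@dataclass
class TraceBuffer:
    """Recorded traces of one run.

    ``events[i, k]`` holds (x, y, z, ux, uy, uz, w) of event k of packet i
    (float32 storage); ``n_events[i]`` the number of recorded events;
    ``terminal[i]`` the final (x, y, z, ux, uy, uz, w, kind) with the exit
    direction already refracted into the terminal medium.  Terminal kind 1
    is a top-surface exit, 2 a bottom exit, 0 death in the medium, 3 a
    capacity overflow (dropped from sampling volumes), 4 a degenerate kill.
    """

    events: np.ndarray
    n_events: np.ndarray
    terminal: np.ndarray
    capacity: int

    @property
    def n_packets(self) -> int:
        return self.events.shape[0]

    @property
    def overflow_count(self) -> int:
        return int(np.sum(self.terminal[:, 7] == 3))

    def terminal_weights(self) -> np.ndarray:
        return self.terminal[:, 6]


@dataclass
class DetectorFiberFilter:
    """Detector-fiber acceptance test applied to terminal packet states.

    A packet is retained when it left through the top surface, its terminal
    position lies inside the core disc and its terminal direction lies
    within the NA cone (NA in air; the terminal direction lives in a medium
    of index ``n_exit``, so the cone is sinθ ≤ NA/n_exit).
    """

    center: tuple[float, float] = (0.0, 0.0)
    core_radius: float = 100e-6
    na: float = 0.22
    n_exit: float = 1.462

    @property
    def cos_min(self) -> float:
        return na_to_cos_min(self.na, self.n_exit)


def filter_traces(buffer: TraceBuffer, detector: DetectorFiberFilter) -> np.ndarray:
    """Indices of packets whose terminal state passes the detector test."""
    t = buffer.terminal
    dx = t[:, 0] - detector.center[0]
    dy = t[:, 1] - detector.center[1]
    ok = (
        (t[:, 7] == TERM_TOP)
        & (dx * dx + dy * dy <= detector.core_radius**2)
        & (np.abs(t[:, 5]) >= detector.cos_min)
    )
    return np.nonzero(ok)[0]


@dataclass
class SamplingVolume:
    """Voxelized sampling volume: Σ path-length × terminal weight per voxel."""

    spec: FluenceGridSpec
    values: np.ndarray
    n_detected: int = 0
    n_launched: int = 0
    total: float = 0.0  # Σ (in-grid path × terminal weight), kernel-side
    dropped_overflow: int = 0

    def normalized(self) -> np.ndarray:
        """Values relative to launch count and voxel volume (units m/m³/packet)."""
        if self.n_launched <= 0:
            raise ValueError("n_launched must be positive for normalization")
        dx, dy, dz = self.spec.voxel_size
        return self.values / (self.n_launched * dx * dy * dz)

    def save_npz(self, path):
        np.savez_compressed(
            path,
            values=self.values,
            origin=np.array(self.spec.origin),
            voxel_size=np.array(self.spec.voxel_size),
            n_detected=self.n_detected,
            n_launched=self.n_launched,
        )

    def export_stack(self, path):
        """Write the volume as a stacked-image text container (one z-slice
        per block) for quick visual inspection."""
        with open(path, "w") as f:
            f.write(f"# sampling volume, shape {self.values.shape}\n")
            for iz in range(self.values.shape[2]):
                f.write(f"# z-slice {iz}\n")
                np.savetxt(f, self.values[:, :, iz])


def compute_sv(buffer: TraceBuffer, selected: np.ndarray,
               grid: FluenceGridSpec) -> SamplingVolume:
    """Voxelize the selected traces onto ``grid``.

    Every inter-event segment is clipped to the grid box and walked voxel
    by voxel; exact intersection lengths are accumulated, each multiplied
    by the packet's terminal weight.
    """
    gx0, gy0, gz0 = grid.origin
    gdx, gdy, gdz = grid.voxel_size
    gnx, gny, gnz = grid.shape
    values = np.zeros(gnx * gny * gnz)
    total = sv_accumulate(
        buffer.events, buffer.n_events, buffer.terminal[:, 6],
        np.asarray(selected, dtype=np.int64),
        gx0, gy0, gz0, gdx, gdy, gdz, gnx, gny, gnz, values,
    )
    return SamplingVolume(
        spec=grid,
        values=values.reshape(gnx, gny, gnz),
        n_detected=int(len(selected)),
        total=float(total),
        dropped_overflow=buffer.overflow_count,
    )


def simulate_sampling_volume(config, detector: DetectorFiberFilter,
                             grid: FluenceGridSpec, n_packets: int,
                             seed: int = 0, batch_size: int = 20_000):
    """Run the layered engine in batches, filter traces against the
    detector fiber, and accumulate the sampling volume.

    Batching bounds the trace memory: a batch of 20k packets with the
    default 1000-event capacity needs ~0.5 GiB of float32 storage.
    Returns the accumulated :class:`SamplingVolume`.
    """
    from .engine import run  # local import to avoid a module cycle
    import copy

    values = np.zeros(grid.shape)
    detected = 0
    launched = 0
    total = 0.0
    dropped = 0
    remaining = int(n_packets)
    batch = 0
    while remaining > 0:
        n = min(batch_size, remaining)
        cfg = copy.copy(config)
        cfg.n_packets = n
        cfg.seed = (seed + 7919 * batch) % (2**31 - 1)
        result = run(cfg)
        buf = result.trace
        sel = filter_traces(buf, detector)
        sv = compute_sv(buf, sel, grid)
        values += sv.values
        total += sv.total
        detected += sv.n_detected
        dropped += sv.dropped_overflow
        launched += n
        remaining -= n
        batch += 1
    return SamplingVolume(
        spec=grid, values=values, n_detected=detected,
        n_launched=launched, total=total, dropped_overflow=dropped,
    )
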