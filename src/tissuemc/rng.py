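"""Random-number streams for the transport kernels.

Two generators are available:

* ``"xoshiro"`` — xoshiro256** seeded through splitmix64; the default.
  Passes BigCrush-class batteries and is the recommended stream.
* ``"ran3"`` — a faithful clone of the subtractive lagged-Fibonacci
  generator ``ran3`` of Numerical Recipes in C.  Shipped because the
  original layered MC reference code uses it and it is known to bias
  simulated reflectance/transmittance; see the validation harness.

A stream is identified by (kind, seed) and is fully reproducible.
"""

from __future__ import annotations

import numpy as np

from ._kernels import draw_uniform

__all__ = ["RngStream", "make_state", "RNG_KINDS"]

RNG_KINDS = {"xoshiro": 0, "ran3": 1}

_MBIG = 1000000000
_MSEED = 161803398


def _splitmix64(state: int):
    state = (state + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = state
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return state, z ^ (z >> 31)


def _xoshiro_state(seed: int) -> np.ndarray:
    s = np.empty(4, dtype=np.uint64)
    state = int(seed) & 0xFFFFFFFFFFFFFFFF
    for i in range(4):
        state, z = _splitmix64(state)
        s[i] = z
    if not s.any():  # all-zero state is invalid
        s[0] = np.uint64(0x9E3779B97F4A7C15)
    return s


def _ran3_state(seed: int):
    """Initialization exactly as in the Numerical Recipes listing."""
    ma = np.zeros(56, dtype=np.int64)
    mj = (_MSEED - int(seed)) % _MBIG
    ma[55] = mj
    mk = 1
    for i in range(1, 55):
        ii = (21 * i) % 55
        ma[ii] = mk
        mk = mj - mk
        if mk < 0:
            mk += _MBIG
        mj = ma[ii]
    for _ in range(4):
        for i in range(1, 56):
            ma[i] -= ma[1 + (i + 30) % 55]
            if ma[i] < 0:
                ma[i] += _MBIG
    return ma, np.array([0, 31], dtype=np.int64)


def make_state(kind: str, seed: int):
    """Kernel-ready state arrays ``(kind_id, su, ma, st)`` for a stream."""
    if kind not in RNG_KINDS:
        raise ValueError(f"unknown RNG kind '{kind}'; choose from {sorted(RNG_KINDS)}")
    su = _xoshiro_state(seed)
    ma, st = _ran3_state(seed)
    return RNG_KINDS[kind], su, ma, st


class RngStream:
    """A seeded uniform-deviate stream usable from Python and the kernels."""

    def __init__(self, kind: str = "xoshiro", seed: int = 0):
        self.kind = kind
        self.seed = int(seed)
        self.kind_id, self.su, self.ma, self.st = make_state(kind, seed)

    def uniform(self, n: int) -> np.ndarray:
        """Draw ``n`` deviates on [0, 1), advancing the stream."""
        out = np.empty(int(n), dtype=np.float64)
        draw_uniform(self.kind_id, self.su, self.ma, self.st, out)
        return out

    def random(self) -> float:
        return float(self.uniform(1)[0])

    def __repr__(self):
        return f"RngStream(kind={self.kind!r}, seed={self.seed})"
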