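"""Fast inline PRNG for the JIT-compiled simulation kernels.

The hybrid Brownian/Gillespie step consumes ~10 random variates per
4 ms step, so variate cost dominates the simulator.  The kernels use an
xorshift128+ generator (period 2^128-1, passes BigCrush except two
linearity tests irrelevant for diffusion noise) seeded via splitmix64,
with Box-Muller normals (pair-cached) and inverse-CDF exponentials.
The Python-level API keeps numpy Generators; only the hot loops use
this generator.

State layout: ``state`` is a uint64 array of length 2; ``cache`` is a
float64 array of length 2 holding a spare normal (slot 0) and a
have-spare flag (slot 1).
"""

import math

import numpy as np
from numba import njit

_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53
TWO_PI = 6.283185307179586


@njit(cache=True)
def seed_state(seed, state, cache):
    """Initialize generator state from an integer seed (splitmix64)."""
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    for i in range(2):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        x = z
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        x = x ^ (x >> np.uint64(31))
        state[i] = x
    if state[0] == np.uint64(0) and state[1] == np.uint64(0):
        state[0] = np.uint64(1)
    cache[1] = 0.0


@njit(cache=True, inline="always")
def next_uniform(state):
    """Uniform double in (0, 1] (never exactly 0, safe for log)."""
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0 ^ (s0 >> np.uint64(26))
    state[1] = s1
    x = (s0 + s1) >> np.uint64(11)
    return (np.float64(x) + 1.0) * _INV_2_53


@njit(cache=True, inline="always")
def next_normal(state, cache):
    """Standard normal (Marsaglia polar method with spare caching)."""
    if cache[1] != 0.0:
        cache[1] = 0.0
        return cache[0]
    while True:
        u = 2.0 * next_uniform(state) - 1.0
        v = 2.0 * next_uniform(state) - 1.0
        s = u * u + v * v
        if 0.0 < s < 1.0:
            break
    m = math.sqrt(-2.0 * math.log(s) / s)
    cache[0] = v * m
    cache[1] = 1.0
    return u * m


@njit(cache=True, inline="always")
def next_exponential(state, scale):
    """Exponential variate with the given mean."""
    return -math.log(next_uniform(state)) * scale
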