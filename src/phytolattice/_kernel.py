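"""Compiled Monte Carlo kernel for the multi-species contact process.

The inner loop performs ``L*L`` paired trials per Monte Carlo step (death
trial then birth trial, each on independently drawn cells) and must run at
hundreds of millions of trials per minute, so it is JIT-compiled with numba
and uses an inline PCG32 generator (O'Neill 2014) rather than numba's
Mersenne Twister, which is several times slower per draw.  All randomness
for one simulation comes from a single PCG32 stream seeded with one 64-bit
integer; draws are consumed in a fixed documented order (death cell, death
Bernoulli if occupied, birth source cell, partner draw if source occupied,
birth Bernoulli if the pair is fertile), so runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint32, uint64

_PCG_MULT = uint64(6364136223846793005)
_PCG_INC = uint64(1442695040888963407)
_INV32 = 2.3283064365386963e-10  # 2**-32


@njit(inline="always")
def _pcg32(state):
    """Advance the PCG32 state; return (new_state, 32 uniform random bits)."""
    old = state
    state = old * _PCG_MULT + _PCG_INC
    xorshifted = uint32(((old >> uint64(18)) ^ old) >> uint64(27))
    rot = uint32(old >> uint64(59))
    out = uint32((xorshifted >> rot) | (xorshifted << ((uint32(0) - rot) & uint32(31))))
    return state, out


@njit(inline="always")
def _runif(state):
    state, bits = _pcg32(state)
    return state, bits * _INV32


@njit(cache=True)
def run_mc(grid, counts, b, m, steps, local, nbr, seed, record_every,
           rec_counts, stop_richness):
    """Run ``steps`` Monte Carlo steps in place.

    Parameters
    ----------
    grid : int8[L*L]
        Flat row-major lattice; 0 = empty, i = one individual of species i.
    counts : int64[N+1]
        Cell counts per state (index 0 = empty); updated in place.
    b, m : float64[N+1]
        Birth/death probability per trial, indexed by species id (0 unused).
    steps : int
        Monte Carlo steps; each is ``L*L`` death+birth trial pairs.
    local : bool
        Von Neumann neighbor births if True, random-distinct-pair otherwise.
    nbr : int32[L*L, 4]
        Periodic von Neumann neighbor table (used only when local).
    seed : uint64
        Stream seed.
    record_every : int
        If > 0, snapshot ``counts`` into ``rec_counts`` every that many steps.
    rec_counts : int64[n_rec, N+1]
        Output buffer for recorded counts.
    stop_richness : int
        Stop early once the number of extant species is <= this value
        (use -1 to never stop, 0 to stop only on total extinction).

    Returns
    -------
    (steps_done, n_recorded)
    """
    state = uint64(seed) * _PCG_MULT + _PCG_INC
    state, _ = _pcg32(state)
    ncells = grid.shape[0]
    nsp = b.shape[0] - 1
    steps_done = 0
    rec_i = 0
    for _step in range(steps):
        for _ in range(ncells):
            # death trial: one uniform cell, emptied w.p. m[species]
            state, u = _runif(state)
            c = int(u * ncells)
            s = grid[c]
            if s != 0:
                state, u = _runif(state)
                if u < m[s]:
                    grid[c] = 0
                    counts[s] -= 1
                    counts[0] += 1
            # birth trial: source cell + partner; (occupied, empty) may breed
            state, u = _runif(state)
            c1 = int(u * ncells)
            s1 = grid[c1]
            if s1 != 0:
                if local:
                    state, u = _runif(state)
                    c2 = nbr[c1, int(u * 4)]
                else:
                    while True:
                        state, u = _runif(state)
                        c2 = int(u * ncells)
                        if c2 != c1:
                            break
                if grid[c2] == 0:
                    state, u = _runif(state)
                    if u < b[s1]:
                        grid[c2] = s1
                        counts[s1] += 1
                        counts[0] -= 1
        steps_done = _step + 1
        if record_every > 0 and steps_done % record_every == 0:
            for k in range(nsp + 1):
                rec_counts[rec_i, k] = counts[k]
            rec_i += 1
        rich = 0
        for k in range(1, nsp + 1):
            if counts[k] > 0:
                rich += 1
        if rich <= stop_richness:
            break
    return steps_done, rec_i


def neighbor_table(L: int) -> np.ndarray:
    """Periodic von Neumann neighbor table for a flat row-major L x L grid."""
    idx = np.arange(L * L).reshape(L, L)
    nbr = np.empty((L * L, 4), dtype=np.int32)
    nbr[:, 0] = np.roll(idx, 1, axis=0).ravel()   # up
    nbr[:, 1] = np.roll(idx, -1, axis=0).ravel()  # down
    nbr[:, 2] = np.roll(idx, 1, axis=1).ravel()   # left
    nbr[:, 3] = np.roll(idx, -1, axis=1).ravel()  # right
    return nbr
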