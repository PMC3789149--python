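"""Multi-species contact process on a periodic L x L lattice.

Every cell holds at most one individual (0 = empty, i = species i).  Time
advances in Monte Carlo steps; one step is ``L*L`` iterations, each
consisting of a death trial (a uniform cell, emptied with probability
``m_i`` if occupied) followed by a birth trial (an independently drawn
source cell plus a partner cell; if the ordered pair is (occupied by i,
empty) the empty cell becomes species i with probability ``b_i``).  Under
local interaction the partner is one of the four von Neumann neighbors
(periodic boundary); under global interaction it is a second uniform cell
distinct from the source, which makes the dynamics mean-field.

The production path (:func:`run_simulation`, :func:`estimate_threshold`)
delegates the inner loop to the compiled kernel in ``_kernel``; the
single-trial functions :func:`death_trial` and :func:`birth_trial` are a
plain-Python statement of the same rules, used for small-scale testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._kernel import neighbor_table, run_mc
from .birth import Community, SpeciesParams, logistic_birth
from .errors import BracketFailureError, ConfigurationError

logger = logging.getLogger(__name__)

_MODES = ("local", "global")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one lattice simulation.

    ``P`` is the nutrient level fixing every species' birth probability;
    ``mode`` selects local (von Neumann) or global (random-pair) births.
    Defaults mirror a full-size run (L = 1000, 20,000 Monte Carlo steps);
    experiments typically scale these down.
    """

    P: float
    mode: str = "local"
    L: int = 1000
    steps: int = 20000
    seed: int = 0
    initial_occupancy: float = 0.3
    record_every: int = 10

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigurationError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.P < 0:
            raise ConfigurationError(f"nutrient level P must be >= 0, got {self.P}")
        if self.L < 2:
            raise ConfigurationError(f"L must be >= 2, got {self.L}")
        if self.steps < 0:
            raise ConfigurationError(f"steps must be >= 0, got {self.steps}")
        if not (0.0 < self.initial_occupancy <= 1.0):
            raise ConfigurationError(
                f"initial_occupancy must be in (0, 1], got {self.initial_occupancy}"
            )
        if self.record_every < 0:
            raise ConfigurationError(
                f"record_every must be >= 0, got {self.record_every}"
            )


@dataclass
class LatticeState:
    """An L x L grid of species identities (0 = empty) with toroidal topology."""

    grid: np.ndarray  # int8, shape (L, L)
    step_count: int = 0

    @property
    def L(self) -> int:
        return self.grid.shape[0]

    def counts(self, n_species: int) -> np.ndarray:
        """Cell counts per state, index 0 = empty, length ``n_species + 1``."""
        return np.bincount(self.grid.ravel(), minlength=n_species + 1).astype(np.int64)

    def densities(self, n_species: int) -> np.ndarray:
        """Per-species densities x_1..x_N (fractions of the L*L cells)."""
        return self.counts(n_species)[1:] / self.grid.size

    def copy(self) -> "LatticeState":
        return LatticeState(self.grid.copy(), self.step_count)


@dataclass
class TimeSeries:
    """Recorded per-species densities and empty density over Monte Carlo steps.

    At every record ``empty + densities.sum()`` equals 1 exactly, because both
    derive from integer cell counts over the same lattice.
    """

    steps: np.ndarray        # int64, shape (R,)
    densities: np.ndarray    # float64, shape (R, N)
    empty: np.ndarray        # float64, shape (R,)

    @property
    def n_species(self) -> int:
        return self.densities.shape[1]

    def to_dataframe(self):
        import pandas as pd

        cols = {"step": self.steps}
        for i in range(self.n_species):
            cols[f"x_{i + 1}"] = self.densities[:, i]
        cols["e"] = self.empty
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class AdjacencyStats:
    """Counts of the 2*L*L von-Neumann-adjacent cell pairs, by pair class."""

    same_species_pairs: int
    cross_species_pairs: int
    species_empty_pairs: int
    empty_empty_pairs: int

    @property
    def total(self) -> int:
        return (self.same_species_pairs + self.cross_species_pairs
                + self.species_empty_pairs + self.empty_empty_pairs)

    @property
    def occupied_pairs(self) -> int:
        """Pairs with both cells occupied (same- plus cross-species)."""
        return self.same_species_pairs + self.cross_species_pairs

    @property
    def cross_fraction(self) -> float:
        """Cross-species share among occupied-occupied pairs (nan if none)."""
        occ = self.occupied_pairs
        return self.cross_species_pairs / occ if occ else float("nan")

    @property
    def same_fraction(self) -> float:
        occ = self.occupied_pairs
        return self.same_species_pairs / occ if occ else float("nan")


# ---------------------------------------------------------------------------
# initialization

def _init_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))


def _kernel_seed(seed: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(1,))
               .generate_state(1, np.uint64)[0] % (2**63))


def init_lattice(cfg: SimConfig, community: Community) -> LatticeState:
    """Random initial condition: ``floor(occupancy * L*L)`` occupied cells,
    split as evenly as possible among the species, placed uniformly without
    collision.  Deterministic given ``cfg.seed``."""
    L, N = cfg.L, community.n
    n_occ = int(cfg.initial_occupancy * L * L)
    rng = _init_rng(cfg.seed)
    positions = rng.permutation(L * L)[:n_occ]
    grid = np.zeros(L * L, dtype=np.int8)
    per = n_occ // N
    extra = n_occ % N
    start = 0
    for i in range(N):
        take = per + (1 if i < extra else 0)
        grid[positions[start:start + take]] = i + 1
        start += take
    return LatticeState(grid.reshape(L, L), step_count=0)


# ---------------------------------------------------------------------------
# single trials (reference implementation of the update rules)

def death_trial(state: LatticeState, community: Community,
                rng: np.random.Generator) -> LatticeState:
    """One death trial in place: a uniform cell, emptied w.p. its mortality."""
    L = state.L
    i, j = rng.integers(0, L, size=2)
    s = state.grid[i, j]
    if s != 0 and rng.random() < community.species[s - 1].mortality:
        state.grid[i, j] = 0
    return state


def birth_trial(state: LatticeState, community: Community, mode: str, P: float,
                rng: np.random.Generator) -> LatticeState:
    """One birth trial in place.

    Draws a source cell and a partner (von Neumann neighbor if local, a
    distinct uniform cell if global); if the ordered pair is (occupied by i,
    empty), the empty cell becomes species i with probability ``b_i(P)``.
    """
    if mode not in _MODES:
        raise ConfigurationError(f"mode must be one of {_MODES}, got {mode!r}")
    if P < 0:
        raise ValueError(f"nutrient level P must be >= 0, got {P}")
    L = state.grid.shape[0]
    i1, j1 = rng.integers(0, L, size=2)
    s1 = state.grid[i1, j1]
    if s1 == 0:
        return state
    if mode == "local":
        di, dj = ((-1, 0), (1, 0), (0, -1), (0, 1))[rng.integers(0, 4)]
        i2, j2 = (i1 + di) % L, (j1 + dj) % L
    else:
        while True:
            i2, j2 = rng.integers(0, L, size=2)
            if (i2, j2) != (i1, j1):
                break
    if state.grid[i2, j2] == 0:
        if rng.random() < logistic_birth(P, community.species[s1 - 1]):
            state.grid[i2, j2] = s1
    return state


def mc_step(state: LatticeState, community: Community, cfg: SimConfig,
            rng: np.random.Generator) -> LatticeState:
    """One Monte Carlo step: ``L*L`` death+birth trial pairs (compiled path).

    Consumes one integer from ``rng`` to seed the kernel stream.
    """
    b, m = _rate_arrays(community, cfg.P)
    counts = state.counts(community.n)
    nbr = neighbor_table(state.L)
    flat = state.grid.reshape(-1)
    seed = int(rng.integers(0, 2**63))
    done, _ = run_mc(flat, counts, b, m, 1, cfg.mode == "local", nbr, seed,
                     0, _EMPTY_REC, -1)
    state.step_count += done
    return state


_EMPTY_REC = np.zeros((0, 1), dtype=np.int64)


def _rate_arrays(community: Community, P: float) -> tuple[np.ndarray, np.ndarray]:
    b = np.concatenate([[0.0], community.birth_rates(P)])
    m = np.concatenate([[0.0], community.mortality])
    return b, m


# ---------------------------------------------------------------------------
# full runs

def run_simulation(cfg: SimConfig, community: Community,
                   stop_richness: int = 0) -> tuple[TimeSeries, LatticeState]:
    """Run ``cfg.steps`` Monte Carlo steps from a random initial lattice.

    Densities are recorded at step 0, every ``cfg.record_every`` steps, and
    at the final step.  Fully reproducible from ``cfg.seed``.

    ``stop_richness`` stops the run early once the number of extant species
    falls to that value; the default 0 stops only on total extinction, in
    which case the (frozen, absorbing) state is carried forward so the
    series still spans all requested steps.
    """
    N = community.n
    state = init_lattice(cfg, community)
    b, m = _rate_arrays(community, cfg.P)
    counts = state.counts(N)
    rec_steps = (np.arange(1, cfg.steps // cfg.record_every + 1) * cfg.record_every
                 if cfg.record_every > 0 else np.empty(0, dtype=np.int64))
    rec_counts = np.zeros((len(rec_steps), N + 1), dtype=np.int64)
    records = [(0, counts.copy())]

    if cfg.steps > 0:
        nbr = neighbor_table(cfg.L)
        done, rec_i = run_mc(state.grid.reshape(-1), counts, b, m, cfg.steps,
                             cfg.mode == "local", nbr, _kernel_seed(cfg.seed),
                             cfg.record_every, rec_counts, stop_richness)
        records += [(int(s), rec_counts[k]) for k, s in enumerate(rec_steps[:rec_i])]
        if done < cfg.steps and int(counts[1:].sum()) == 0:
            # total extinction is absorbing: extend the frozen state
            records += [(int(s), counts.copy()) for s in rec_steps[rec_i:]]
            done = cfg.steps
        if records[-1][0] != done:
            records.append((done, counts.copy()))
        state.step_count = done

    steps_arr = np.array([s for s, _ in records], dtype=np.int64)
    cmat = np.stack([c for _, c in records])
    series = TimeSeries(steps_arr, cmat[:, 1:] / cfg.L**2, cmat[:, 0] / cfg.L**2)
    if logger.isEnabledFor(logging.INFO):
        for s, c in records:
            if s % 1000 == 0 or s == records[-1][0]:
                logger.info("step %6d  total density %.4f  richness %d",
                            s, c[1:].sum() / cfg.L**2, int((c[1:] > 0).sum()))
    return series, state


def run_single_species(b: float, m: float, mode: str, L: int, steps: int,
                       seed: int, initial_occupancy: float = 0.3) -> float:
    """Final density of a single species with a constant birth probability.

    Bypasses the nutrient-to-birth-rate mapping: ``b`` is used directly as
    the per-trial birth probability.  Used by threshold scans.
    """
    cfg = SimConfig(P=0.0, mode=mode, L=L, steps=steps, seed=seed,
                    initial_occupancy=initial_occupancy, record_every=0)
    state = init_lattice(cfg, Community((SpeciesParams(1, 0.5, 1.0, mortality=m),)))
    counts = state.counts(1)
    nbr = neighbor_table(L)
    run_mc(state.grid.reshape(-1), counts, np.array([0.0, b]), np.array([0.0, m]),
           steps, mode == "local", nbr, _kernel_seed(seed), 0,
           np.zeros((0, 2), dtype=np.int64), 0)
    return counts[1] / L**2


# ---------------------------------------------------------------------------
# measurements

def richness(obj) -> int:
    """Number of species with at least one individual.

    Accepts a :class:`LatticeState` or a per-species density/count vector.
    """
    if isinstance(obj, LatticeState):
        return int(len(np.unique(obj.grid[obj.grid > 0])))
    arr = np.asarray(obj, dtype=float)
    return int(np.count_nonzero(arr > 0.0))


def adjacency_stats(state: LatticeState) -> AdjacencyStats:
    """Classify all ``2*L*L`` right/down periodic neighbor pairs."""
    g = state.grid
    same = cross = mixed = empty = 0
    for other in (np.roll(g, -1, axis=0), np.roll(g, -1, axis=1)):
        a_occ, b_occ = g > 0, other > 0
        both = a_occ & b_occ
        same += int(np.count_nonzero(both & (g == other)))
        cross += int(np.count_nonzero(both & (g != other)))
        mixed += int(np.count_nonzero(a_occ ^ b_occ))
        empty += int(np.count_nonzero(~a_occ & ~b_occ))
    return AdjacencyStats(same, cross, mixed, empty)


def estimate_threshold(mode: str, mortality: float, L: int, steps: int,
                       b_grid: Sequence[float], replicates: int, seed: int,
                       initial_occupancy: float = 0.3) -> float:
    """Critical birth probability from a grid scan of single-species runs.

    Scans ``b_grid`` in ascending order; at each value runs seeded
    replicates (constant birth probability, no nutrient mapping) and returns
    the smallest value whose final density is positive in a majority of
    replicates.  Replicate seeds depend only on (seed, grid index,
    replicate index), so early exit once a majority is settled does not
    change the estimate.

    A result equal to the grid minimum means the bracket may not contain
    the transition (e.g. zero mortality).  If no grid value persists, raises
    :class:`BracketFailureError`.
    """
    b_grid = np.asarray(b_grid, dtype=float)
    if np.any(np.diff(b_grid) <= 0) or np.any((b_grid <= 0) | (b_grid >= 1)):
        raise ValueError("b_grid must be strictly ascending within (0, 1)")
    majority = replicates // 2 + 1
    for bi, b in enumerate(b_grid):
        survivors = 0
        for r in range(replicates):
            rep_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(bi, r))
                           .generate_state(1, np.uint64)[0] % (2**63))
            dens = run_single_species(float(b), mortality, mode, L, steps,
                                      rep_seed, initial_occupancy)
            if dens > 0:
                survivors += 1
            if survivors >= majority:
                logger.info("threshold scan: b=%.3f persists (%d/%d)", b,
                            survivors, replicates)
                return float(b)
            if survivors + (replicates - 1 - r) < majority:
                break
    raise BracketFailureError(
        f"no persistence anywhere on the grid [{b_grid[0]}, {b_grid[-1]}]"
    )
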