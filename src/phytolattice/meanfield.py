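"""Mean-field theory of the multi-species contact process.

Ignoring spatial correlation (exact for global interaction in the
infinite-lattice limit), the per-species densities obey

    dx_i/dt = -m_i x_i + b_i x_i e,        e = 1 - sum_j x_j,

with time measured in Monte Carlo steps.  For N = 1 this is the logistic
equation with nontrivial equilibrium x* = 1 - m/b; for N = 2 it is the
Lotka-Volterra competition model.  Rewriting

    dx_i/dt = R_i x_i (1 - (x_1 + x_2) / K_i)

requires R_i (1 - (x1+x2)/K_i) = -m_i + b_i (1 - x1 - x2) identically,
which fixes R_i = b_i - m_i and K_i = (b_i - m_i)/b_i.  Both species see
the same competitor combination x_1 + x_2 with weight 1/K_i, so the usual
coexistence inequalities (each species able to invade the other's
equilibrium) cannot hold simultaneously: the species with the larger
carrying density K excludes the other, and a tie K_1 = K_2 is a
structurally unstable degeneracy.  Generic coexistence is impossible for
any N >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .birth import Community, SpeciesParams, logistic_birth
from .errors import ConfigurationError

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class MeanFieldSystem:
    """The ODE system for one community at a fixed nutrient level."""

    community: Community
    P: float

    @property
    def dimension(self) -> int:
        return self.community.n

    @property
    def b(self) -> np.ndarray:
        return self.community.birth_rates(self.P)

    @property
    def m(self) -> np.ndarray:
        return self.community.mortality


@dataclass(frozen=True)
class LVParams:
    """Lotka-Volterra form of one species: growth rate R and carrying density K."""

    R: float
    K: float


@dataclass(frozen=True)
class MFTrajectory:
    """An integrated mean-field trajectory (time in Monte Carlo steps)."""

    t: np.ndarray  # (R,)
    x: np.ndarray  # (R, N)

    @property
    def empty(self) -> np.ndarray:
        return 1.0 - self.x.sum(axis=1)

    def to_dataframe(self):
        import pandas as pd

        cols = {"t": self.t}
        for i in range(self.x.shape[1]):
            cols[f"x_{i + 1}"] = self.x[:, i]
        cols["e"] = self.empty
        return pd.DataFrame(cols)


def competition_rhs(x: np.ndarray, b, m) -> np.ndarray:
    """Raw right-hand side ``x * (-m + b * e)``, vectorized over leading axes."""
    e = 1.0 - x.sum(axis=-1, keepdims=True)
    return x * (-np.asarray(m) + np.asarray(b) * e)


def mf_rhs(x, sys: MeanFieldSystem) -> np.ndarray:
    """Derivative vector of the mean-field system at densities ``x``.

    Raises
    ------
    ValueError
        If ``x`` is not on the simplex (negative entries or total > 1).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (sys.dimension,):
        raise ValueError(f"expected density vector of length {sys.dimension}")
    if np.any(x < -_SIMPLEX_TOL) or x.sum() > 1.0 + _SIMPLEX_TOL:
        raise ValueError(f"densities must satisfy x >= 0 and sum(x) <= 1, got {x}")
    return competition_rhs(x, sys.b, sys.m)


def _rk4(x0: np.ndarray, b, m, T: float, dt: float,
         record_every: int) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step classical Runge-Kutta; clips densities at 0 after each step.

    ``x0`` may carry leading batch axes; ``b``/``m`` broadcast against it.
    """
    n_steps = int(round(T / dt))
    x = np.array(x0, dtype=float)
    ts = [0.0]
    xs = [x.copy()]
    for k in range(1, n_steps + 1):
        k1 = competition_rhs(x, b, m)
        k2 = competition_rhs(x + 0.5 * dt * k1, b, m)
        k3 = competition_rhs(x + 0.5 * dt * k2, b, m)
        k4 = competition_rhs(x + dt * k3, b, m)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        np.clip(x, 0.0, None, out=x)
        if k % record_every == 0 or k == n_steps:
            ts.append(k * dt)
            xs.append(x.copy())
    return np.array(ts), np.stack(xs)


def integrate_mf(x0, sys: MeanFieldSystem, T: float, dt: float = 0.01,
                 record_every: int | None = None) -> MFTrajectory:
    """Integrate the mean-field ODE with fixed-step 4th-order Runge-Kutta.

    ``record_every`` counts integrator steps between stored points; the
    default stores roughly one point per unit time.  Densities are clipped
    at zero after every step, so trajectories stay on the simplex.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be positive, got {dt}")
    if T < 0:
        raise ConfigurationError(f"T must be >= 0, got {T}")
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (sys.dimension,):
        raise ValueError(f"expected x0 of length {sys.dimension}")
    if np.any(x0 < 0) or x0.sum() > 1.0 + _SIMPLEX_TOL:
        raise ValueError("x0 must lie on the simplex")
    if record_every is None:
        record_every = max(1, int(round(1.0 / dt)))
    if T == 0:
        return MFTrajectory(np.zeros(1), x0[None, :].copy())
    ts, xs = _rk4(x0, sys.b, sys.m, T, dt, record_every)
    return MFTrajectory(ts, xs)


def single_species_equilibrium(b: float, m: float) -> float:
    """Nontrivial logistic equilibrium ``max(0, 1 - m/b)``."""
    if b <= 0:
        raise ValueError(f"birth rate must be positive, got {b}")
    return max(0.0, 1.0 - m / b)


def lv_mapping(b1: float, m1: float, b2: float, m2: float) -> tuple[LVParams, LVParams]:
    """Map two-species mean-field rates to Lotka-Volterra (R_i, K_i).

    ``R_i = b_i - m_i`` and ``K_i = (b_i - m_i)/b_i`` (see the module
    docstring for the identification); ``K_i`` coincides with the species'
    single-species equilibrium density.
    """
    if b1 <= 0 or b2 <= 0:
        raise ValueError("birth rates must be positive")
    return (LVParams(b1 - m1, (b1 - m1) / b1), LVParams(b2 - m2, (b2 - m2) / b2))


def classify_from_rates(b1: float, m1: float, b2: float, m2: float) -> str:
    """Stationary-state class of the two-species competition at given rates.

    Returns one of ``both_extinct``, ``species1_only``, ``species2_only``,
    ``degenerate``; ``coexist`` is in the label set for completeness but is
    unreachable here, because both species compete for the single resource
    (space) and the invasibility inequalities cannot hold simultaneously.
    """
    p1, p2 = lv_mapping(b1, m1, b2, m2)
    if p1.R <= 0 and p2.R <= 0:
        return "both_extinct"
    if p1.R > 0 and p2.R <= 0:
        return "species1_only"
    if p2.R > 0 and p1.R <= 0:
        return "species2_only"
    if p1.K > p2.K:
        return "species1_only"
    if p2.K > p1.K:
        return "species2_only"
    return "degenerate"


def classify_equilibrium(sp1: SpeciesParams, sp2: SpeciesParams, P: float) -> str:
    """Stationary-state class for two species at nutrient level ``P``."""
    return classify_from_rates(
        float(logistic_birth(P, sp1)), sp1.mortality,
        float(logistic_birth(P, sp2)), sp2.mortality,
    )
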