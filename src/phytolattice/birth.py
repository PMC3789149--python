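"""Nutrient-dependent logistic birth-rate curves and community construction.

Each phytoplankton species reproduces into empty lattice sites with a
per-trial probability that rises sigmoidally with the ambient nutrient
level ``P`` (a Monod-like saturation curve for the nutrient range where
growth is positive).  The curve for species *i* is the three-parameter
logistic anchored at the origin,

    b_i(P) = b_max / (1 + C * exp(-k * P)),      C = b_max / b0 - 1,

so that b_i(0) = b0 (a vanishingly small baseline, 1e-6 by default) and
b_i(P) -> b_max as P -> infinity.

A community of N species is built so that every curve passes through one
common pivot point (pivot_P, pivot_b).  Because the curves share a pivot
but saturate at pairwise-distinct maxima, the classic oligotrophy
tradeoff holds automatically: the species ranked fastest at high
nutrients is ranked slowest below the pivot, and the spread of birth
rates widens with enrichment.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import InfeasibleParametersError

#: Birth probability at P = 0 shared by every species.
B0_DEFAULT = 1e-6

#: Community-wide mortality per trial under local (von Neumann) interaction.
MORTALITY_LOCAL = 0.3

#: Community-wide mortality per trial under global (random-pair) interaction.
MORTALITY_GLOBAL = 0.5

#: Nutrient level at which all default curves intersect.
PIVOT_P_DEFAULT = 14.2

#: Common birth probability at the pivot, just above the extinction threshold.
PIVOT_B_DEFAULT = 0.545

#: Range of saturation birth probabilities spanned by a default community.
B_MAX_RANGE = (0.90, 0.60)


@dataclass(frozen=True)
class SpeciesParams:
    """One species' logistic birth-rate curve plus its mortality.

    Parameters
    ----------
    species_id:
        Positive integer identity; doubles as the cell value on the lattice.
    b_max:
        Saturation birth probability per trial as ``P -> inf``; in (0, 1].
    steepness:
        Logistic rate constant ``k`` in 1/nutrient-units; positive.
    b0:
        Birth probability at ``P = 0``; must satisfy ``0 < b0 < b_max``.
    mortality:
        Death probability per trial; in [0, 1].
    """

    species_id: int
    b_max: float
    steepness: float
    b0: float = B0_DEFAULT
    mortality: float = MORTALITY_LOCAL

    def __post_init__(self) -> None:
        if self.species_id < 1:
            raise ValueError(f"species_id must be >= 1, got {self.species_id}")
        if not (0.0 < self.b0 < self.b_max <= 1.0):
            raise ValueError(
                f"need 0 < b0 < b_max <= 1, got b0={self.b0}, b_max={self.b_max}"
            )
        if self.steepness <= 0.0:
            raise ValueError(f"steepness must be positive, got {self.steepness}")
        if not (0.0 <= self.mortality <= 1.0):
            raise ValueError(f"mortality must be in [0, 1], got {self.mortality}")


def logistic_birth(P, sp: SpeciesParams):
    """Birth probability of species ``sp`` at nutrient level ``P``.

    Evaluates ``b_max / (1 + C exp(-k P))`` with ``C = b_max/b0 - 1`` so the
    curve passes through ``(0, b0)`` and saturates at ``b_max``; it is
    strictly increasing in ``P``.  ``P`` may be a scalar or an array.

    Raises
    ------
    ValueError
        If any ``P`` is negative.
    """
    P_arr = np.asarray(P, dtype=float)
    if np.any(P_arr < 0.0):
        raise ValueError(f"nutrient level P must be >= 0, got {P}")
    C = sp.b_max / sp.b0 - 1.0
    out = sp.b_max / (1.0 + C * np.exp(-sp.steepness * P_arr))
    return out if isinstance(out, np.ndarray) and out.ndim else float(out)


def solve_steepness(b_max: float, pivot_P: float, pivot_b: float,
                    b0: float = B0_DEFAULT) -> float:
    """Steepness ``k`` such that the curve passes through ``(pivot_P, pivot_b)``.

    Inverts the logistic exactly:  ``k = -ln(((b_max/pivot_b) - 1)/C) / pivot_P``.
    """
    if not (b0 < pivot_b < b_max):
        raise InfeasibleParametersError(
            f"pivot_b must lie in (b0, b_max) = ({b0}, {b_max}), got {pivot_b}"
        )
    if pivot_P <= 0.0:
        raise InfeasibleParametersError(f"pivot_P must be positive, got {pivot_P}")
    C = b_max / b0 - 1.0
    return -math.log((b_max / pivot_b - 1.0) / C) / pivot_P


@dataclass(frozen=True)
class Community:
    """An ordered collection of species sharing one lattice ecosystem.

    ``pivot_P``/``pivot_b`` record the common intersection point when the
    community was built by :func:`default_community`; they are ``None`` for
    hand-assembled communities.  Strong invariants (pairwise-distinct
    ``b_max``, shared ``b0`` and mortality) are guaranteed by the generator,
    not by this container, so that degenerate communities remain
    representable for diagnostic checks.
    """

    species: tuple[SpeciesParams, ...]
    pivot_P: float | None = None
    pivot_b: float | None = None

    def __post_init__(self) -> None:
        if len(self.species) == 0:
            raise ValueError("community must contain at least one species")
        ids = [sp.species_id for sp in self.species]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("species_id values must be 1..N in order")

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def b_max_values(self) -> np.ndarray:
        return np.array([sp.b_max for sp in self.species])

    @property
    def mortality(self) -> np.ndarray:
        """Per-species mortality, index aligned with species order."""
        return np.array([sp.mortality for sp in self.species])

    def birth_rates(self, P) -> np.ndarray:
        """Vector of birth probabilities at nutrient level ``P``."""
        return np.array([logistic_birth(P, sp) for sp in self.species])

    def with_mortality(self, mortality: float) -> "Community":
        """Copy of the community with a community-wide mortality."""
        return Community(
            tuple(replace(sp, mortality=mortality) for sp in self.species),
            pivot_P=self.pivot_P,
            pivot_b=self.pivot_b,
        )

    # -- serialization -----------------------------------------------------

    def to_csv(self, path) -> None:
        """Write ``species_id,b_max,steepness,b0,mortality`` rows."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["species_id", "b_max", "steepness", "b0", "mortality"])
            for sp in self.species:
                writer.writerow(
                    [sp.species_id, repr(sp.b_max), repr(sp.steepness),
                     repr(sp.b0), repr(sp.mortality)]
                )

    @classmethod
    def from_csv(cls, path) -> "Community":
        species = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                species.append(
                    SpeciesParams(
                        species_id=int(row["species_id"]),
                        b_max=float(row["b_max"]),
                        steepness=float(row["steepness"]),
                        b0=float(row["b0"]),
                        mortality=float(row["mortality"]),
                    )
                )
        return cls(tuple(species))


def default_community(
    N: int,
    pivot_P: float = PIVOT_P_DEFAULT,
    pivot_b: float = PIVOT_B_DEFAULT,
    b_max_values: Sequence[float] | None = None,
    b0: float = B0_DEFAULT,
    mortality: float = MORTALITY_LOCAL,
) -> Community:
    """Construct an ``N``-species community with a common pivot point.

    Every curve is solved to pass through ``(pivot_P, pivot_b)`` exactly.
    With pairwise-distinct saturation levels this forces the oligotrophy
    tradeoff: below the pivot the species ranking by birth rate is the
    reverse of the ranking by ``b_max``, and above it the curves diverge.
    The default ``b_max`` grid is an evenly spaced descending grid on
    [0.60, 0.90] (species 1 fastest at high nutrients).
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if b_max_values is None:
        b_max_values = np.linspace(B_MAX_RANGE[0], B_MAX_RANGE[1], N)
    b_max_values = np.asarray(b_max_values, dtype=float)
    if len(b_max_values) != N:
        raise InfeasibleParametersError(
            f"expected {N} b_max values, got {len(b_max_values)}"
        )
    if len(np.unique(b_max_values)) != N:
        raise InfeasibleParametersError("b_max values must be pairwise distinct")
    if pivot_b >= b_max_values.min() or pivot_b <= b0:
        raise InfeasibleParametersError(
            f"pivot_b={pivot_b} must lie in (b0, min(b_max)) = "
            f"({b0}, {b_max_values.min()})"
        )
    species = tuple(
        SpeciesParams(
            species_id=i + 1,
            b_max=float(bm),
            steepness=solve_steepness(float(bm), pivot_P, pivot_b, b0),
            b0=b0,
            mortality=mortality,
        )
        for i, bm in enumerate(b_max_values)
    )
    return Community(species, pivot_P=pivot_P, pivot_b=pivot_b)


def tradeoff_check(c: Community, P_low: float, P_high: float) -> bool:
    """True iff the community shows the oligotrophy tradeoff between two levels.

    The ranking of species by birth rate at ``P_low`` must be the exact
    reverse of the ranking at ``P_high`` (both rankings strict: any tie
    fails), and the spread (max - min) of birth rates at ``P_high`` must
    exceed the spread at ``P_low``.
    """
    if c.pivot_P is not None and not (P_low < c.pivot_P < P_high):
        raise ValueError(
            f"need P_low < pivot_P < P_high, got {P_low}, {c.pivot_P}, {P_high}"
        )
    lo = c.birth_rates(P_low)
    hi = c.birth_rates(P_high)
    if len(np.unique(lo)) != c.n or len(np.unique(hi)) != c.n:
        return False  # no strict ordering exists
    if not np.array_equal(np.argsort(lo), np.argsort(hi)[::-1]):
        return False
    return float(hi.max() - hi.min()) > float(lo.max() - lo.min())
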