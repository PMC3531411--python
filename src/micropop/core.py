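"""Domain types and validation shared by all micropop modules.

The model describes a micro-population (e.g. cells in a microdroplet) as a
mixture of metabolic phenotypes. Each phenotype i has a division rate
``rate`` (divisions per unit time) and a ``yield_`` (divisions supported per
unit of growth-limiting resource); one division of type i consumes
``cost = 1/yield_`` units of resource. Growth starts from an inoculum
(per-type initial counts) in a finite resource budget S0 and stops when the
resource is exhausted.

Conventions (removing redundant scales):
  * the reference yield is y1 = 1, so the budget is measured in
    "type-1 divisions";
  * the reference rate is lambda1 = 1; division-sequence (jump-chain)
    distributions depend only on rate ratios, only event times rescale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: relative tolerance for floating-point invariant checks
REL_TOL = 1e-9


class MicropopError(Exception):
    """Base class for all micropop errors."""


class InvalidParameterError(MicropopError, ValueError):
    """A model parameter violates its invariant ("invalid-parameter")."""


class ExtinctPopulationError(MicropopError):
    """All per-type counts are zero ("extinct-population")."""


class InstanceTooLargeError(MicropopError):
    """Exact solver guard exceeded ("instance-too-large")."""


class PreconditionError(MicropopError):
    """An operation's precondition does not hold ("precondition-violated")."""


class NoRootError(MicropopError):
    """Degenerate stopping-time problem ("no-root")."""


class OutOfSupportError(MicropopError, ValueError):
    """Query point outside the distribution's support ("out-of-support")."""


class ToleranceUnreachableError(MicropopError):
    """Requested rational approximation needs denominators > guard."""


@dataclass(frozen=True)
class MetabolicType:
    """One metabolic phenotype.

    Parameters
    ----------
    rate
        Division rate lambda_i > 0, divisions per unit time.
    yield_
        Yield y_i > 0, divisions supported per unit resource. The resource
        consumed by one division is ``cost = 1/yield_``.
    """

    rate: float
    yield_: float

    def __post_init__(self) -> None:
        if not (self.rate > 0 and math.isfinite(self.rate)):
            raise InvalidParameterError(f"invalid-parameter: rate must be positive, got {self.rate}")
        if not (self.yield_ > 0 and math.isfinite(self.yield_)):
            raise InvalidParameterError(f"invalid-parameter: yield must be positive, got {self.yield_}")

    @property
    def cost(self) -> float:
        """Resource consumed per division, 1/yield."""
        return 1.0 / self.yield_


def cost_of(t: MetabolicType) -> float:
    """Resource consumed by one division of type ``t`` (= 1/yield)."""
    return t.cost


@dataclass(frozen=True)
class DropletSpec:
    """The initial condition of one droplet experiment.

    Fields
    ------
    types
        The metabolic phenotypes present.
    initial_counts
        Inoculum: number of cells of each type, n_i(0) >= 0 with total >= 1.
    budget
        Initial amount of the growth-limiting resource, S0 > 0.
    """

    types: tuple[MetabolicType, ...]
    initial_counts: tuple[int, ...]
    budget: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "types", tuple(self.types))
        object.__setattr__(self, "initial_counts", tuple(int(c) for c in self.initial_counts))
        validate_droplet(self)

    # -- convenience views -------------------------------------------------
    @property
    def n_types(self) -> int:
        return len(self.types)

    @property
    def rates(self) -> np.ndarray:
        return np.array([t.rate for t in self.types], dtype=float)

    @property
    def yields(self) -> np.ndarray:
        return np.array([t.yield_ for t in self.types], dtype=float)

    @property
    def costs(self) -> np.ndarray:
        return np.array([t.cost for t in self.types], dtype=float)

    @property
    def counts(self) -> np.ndarray:
        return np.array(self.initial_counts, dtype=np.int64)

    @property
    def total_inoculum(self) -> int:
        return int(sum(self.initial_counts))

    @classmethod
    def from_arrays(
        cls,
        counts: Sequence[int],
        rates: Sequence[float],
        yields: Sequence[float],
        budget: float,
    ) -> "DropletSpec":
        """Build a spec from parallel per-type parameter lists."""
        if len(rates) != len(yields):
            raise InvalidParameterError("invalid-parameter: rates and yields length mismatch")
        types = tuple(MetabolicType(rate=r, yield_=y) for r, y in zip(rates, yields))
        return cls(types=types, initial_counts=tuple(counts), budget=float(budget))

    def swapped(self) -> "DropletSpec":
        """Return the spec with the two type labels exchanged (two-type only)."""
        if self.n_types != 2:
            raise PreconditionError("precondition-violated: label swap defined for two types")
        return DropletSpec(
            types=(self.types[1], self.types[0]),
            initial_counts=(self.initial_counts[1], self.initial_counts[0]),
            budget=self.budget,
        )


def validate_droplet(spec: DropletSpec) -> DropletSpec:
    """Check all DropletSpec invariants; return the spec unchanged.

    Raises
    ------
    InvalidParameterError
        Naming the offending field, for non-positive rates/yields/budget,
        an empty type list, a zero total inoculum, or a length mismatch.
    """
    if len(spec.types) == 0:
        raise InvalidParameterError("invalid-parameter: types must be non-empty")
    if len(spec.initial_counts) != len(spec.types):
        raise InvalidParameterError(
            "invalid-parameter: initial_counts length "
            f"{len(spec.initial_counts)} != number of types {len(spec.types)}"
        )
    if any(c < 0 for c in spec.initial_counts):
        raise InvalidParameterError("invalid-parameter: inoculum counts must be non-negative")
    if sum(spec.initial_counts) < 1:
        raise InvalidParameterError("invalid-parameter: inoculum must contain at least one cell")
    if not (spec.budget > 0 and math.isfinite(spec.budget)):
        raise InvalidParameterError(f"invalid-parameter: budget must be positive, got {spec.budget}")
    for t in spec.types:
        # MetabolicType validates itself on construction; re-check the
        # cross-invariant cost * yield = 1 defensively.
        if abs(t.cost * t.yield_ - 1.0) > REL_TOL:
            raise InvalidParameterError("invalid-parameter: cost * yield != 1")
    return spec


def two_type_droplet(
    n0: int,
    budget: float,
    rate_ratio: float = 1.0,
    yield_ratio: float = 1.0,
    split: tuple[int, int] | None = None,
) -> DropletSpec:
    """Convenience constructor for the canonical two-type droplet.

    Type 1 is the reference (rate 1, yield 1); type 2 is the faster grower
    with rate ``rate_ratio`` >= 1 and yield ``yield_ratio`` (= r, the yield
    ratio y2/y1; r < 1 is a metabolic tradeoff). The inoculum is split
    half/half unless ``split`` is given (odd ``n0`` puts the extra cell in
    type 1).
    """
    if rate_ratio < 1.0:
        raise InvalidParameterError("invalid-parameter: rate_ratio must be >= 1 (type 2 is the faster grower)")
    if split is None:
        split = (n0 - n0 // 2, n0 // 2)
    if sum(split) != n0:
        raise InvalidParameterError("invalid-parameter: split must sum to n0")
    return DropletSpec.from_arrays(
        counts=split, rates=[1.0, rate_ratio], yields=[1.0, yield_ratio], budget=budget
    )


@dataclass(frozen=True)
class TwoTypeParams:
    """Dimensionless parameters of the two-type analysis.

    ``ratio_rates`` = lambda2/lambda1 >= 1 with type 2 the faster grower
    (types are relabelled on construction to enforce this, recorded in
    ``swapped``); ``ratio_yields`` = r = y2/y1 (r < 1 means metabolic
    tradeoff: the faster grower has the lower yield); ``epsilon`` is the
    small parameter of the deterministic expansion, the inoculum scale
    relative to the number of divisions supported by the budget,
    epsilon = N0 / (2 * y2 * S0).
    """

    ratio_rates: float
    ratio_yields: float
    epsilon: float
    swapped: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.ratio_rates < 1.0:
            raise InvalidParameterError("invalid-parameter: ratio_rates must be >= 1 after relabelling")
        for name in ("ratio_rates", "ratio_yields", "epsilon"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise InvalidParameterError(f"invalid-parameter: {name} must be positive, got {v}")

    @classmethod
    def from_droplet(cls, spec: DropletSpec) -> "TwoTypeParams":
        """Extract the canonical dimensionless parameters of a two-type spec.

        Relabels so that index 2 is the (weakly) faster grower, which makes
        r < 1 equivalent to a growth/yield tradeoff.
        """
        if spec.n_types != 2:
            raise PreconditionError("precondition-violated: two types required")
        r1, r2 = (t.rate for t in spec.types)
        swap = r2 < r1
        if swap:
            spec = spec.swapped()
        t1, t2 = spec.types
        n0 = spec.total_inoculum
        return cls(
            ratio_rates=t2.rate / t1.rate,
            ratio_yields=t2.yield_ / t1.yield_,
            epsilon=n0 / (2.0 * t2.yield_ * spec.budget),
            swapped=swap,
        )
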