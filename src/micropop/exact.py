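"""Exact final-state distributions on the stopping set.

The division sequence of a two-type droplet is a monotone random walk on
the lattice of division counts (d1, d2). A walk is absorbed at the first
point where cumulative resource consumption ``c1*d1 + c2*d2`` reaches the
budget (overshoot rule: the last division executes in full). Two exact
solvers compute the absorbed-mass distribution:

* :func:`enumerate_paths` — exhaustive depth-first enumeration of all
  division sequences with their step-probability products (tiny instances);
* :func:`forward_dp` — forward propagation of probability mass over
  anti-diagonals of constant total division count, so every state's
  predecessors are finalized before it is processed (moderate instances).

These are the ground-truth oracles against which the simulators and the
urn analytics are checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core import (
    DropletSpec,
    InstanceTooLargeError,
    PreconditionError,
    validate_droplet,
)
from .simulate import resource_remains

Observable = Literal["d1", "d2", "n_final", "fraction1", "consumed"]

#: default guards (configurable per call) keeping exact solvers desk-scale
ENUM_GUARD = 20
DP_GUARD = 5_000


@dataclass
class FinalStateDistribution:
    """Probability table over trajectory endpoints on the stopping set.

    ``d_counts[j]`` is the j-th support point (divisions per type),
    ``probs[j]`` its probability. Exact methods normalize to 1 within
    1e-12; the ``empirical`` method stores observed frequencies.
    """

    spec: DropletSpec
    d_counts: np.ndarray  # (n_support, n_types) int
    probs: np.ndarray  # (n_support,)
    method: str  # enumerate | dp | empirical
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_lattice(cls, spec, d_counts, probs, method, meta=None):
        d_counts = np.asarray(d_counts, dtype=np.int64)
        probs = np.asarray(probs, dtype=float)
        order = np.lexsort(d_counts.T[::-1])  # canonical support order
        return cls(
            spec=spec,
            d_counts=d_counts[order],
            probs=probs[order],
            method=method,
            meta=dict(meta or {}),
        )

    @property
    def n_final(self) -> np.ndarray:
        return self.d_counts.sum(axis=1) + self.spec.total_inoculum

    @property
    def consumed(self) -> np.ndarray:
        return self.d_counts @ self.spec.costs

    def observable_values(self, observable: Observable) -> np.ndarray:
        if observable == "d1":
            return self.d_counts[:, 0].astype(float)
        if observable == "d2":
            return self.d_counts[:, 1].astype(float)
        if observable == "n_final":
            return self.n_final.astype(float)
        if observable == "consumed":
            return self.consumed
        if observable == "fraction1":
            # final fraction of type-1 cells in the population
            return (self.d_counts[:, 0] + self.spec.initial_counts[0]) / self.n_final
        raise ValueError(f"unknown observable {observable!r}")

    def marginal(self, observable: Observable) -> tuple[np.ndarray, np.ndarray]:
        """Induced distribution (values, probs) of an observable."""
        vals = self.observable_values(observable)
        uniq, inv = np.unique(vals, return_inverse=True)
        p = np.zeros_like(uniq, dtype=float)
        np.add.at(p, inv, self.probs)
        return uniq, p

    def pmf(self, observable: Observable, value: float) -> float:
        vals, p = self.marginal(observable)
        hit = np.isclose(vals, value, rtol=0, atol=1e-9)
        return float(p[hit].sum())

    def cdf(self, observable: Observable, value: float) -> float:
        vals, p = self.marginal(observable)
        return float(p[vals <= value + 1e-9].sum())

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "d_type1": self.d_counts[:, 0],
                "d_type2": self.d_counts[:, 1],
                "n_final": self.n_final,
                "consumed": self.consumed,
                "prob": self.probs,
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Moments:
    mean: float
    variance: float
    m3: float  # third central moment
    m4: float  # fourth central moment

    @property
    def std(self) -> float:
        return math.sqrt(max(self.variance, 0.0))

    @property
    def cv(self) -> float:
        return self.std / self.mean if self.mean != 0 else math.inf


def distribution_moments(dist: FinalStateDistribution, observable: Observable) -> Moments:
    """Exact mean, variance and higher central moments of an observable."""
    vals, p = dist.marginal(observable)
    mean = float(np.dot(p, vals))
    dev = vals - mean
    return Moments(
        mean=mean,
        variance=float(np.dot(p, dev**2)),
        m3=float(np.dot(p, dev**3)),
        m4=float(np.dot(p, dev**4)),
    )


def tv_distance(a: FinalStateDistribution, b: FinalStateDistribution, observable: Observable = "d1") -> float:
    """Total-variation distance between induced observable distributions."""
    va, pa = a.marginal(observable)
    vb, pb = b.marginal(observable)
    union = np.union1d(va, vb)
    qa = np.zeros(union.size)
    qb = np.zeros(union.size)
    qa[np.searchsorted(union, va)] = pa
    qb[np.searchsorted(union, vb)] = pb
    return 0.5 * float(np.abs(qa - qb).sum())


def _check_two_types(spec: DropletSpec) -> None:
    if spec.n_types != 2:
        raise PreconditionError("precondition-violated: exact solvers are two-type only")


def max_divisions(spec: DropletSpec) -> int:
    """Upper bound on the number of divisions under the overshoot rule."""
    return int(np.ceil(spec.budget / spec.costs.min()))


def enumerate_paths(spec: DropletSpec, guard: int = ENUM_GUARD) -> FinalStateDistribution:
    """Exact endpoint distribution by exhaustive path enumeration."""
    validate_droplet(spec)
    _check_two_types(spec)
    if max_divisions(spec) > guard:
        raise InstanceTooLargeError(
            f"instance-too-large: up to {max_divisions(spec)} divisions exceeds enumeration guard {guard}"
        )
    r1, r2 = spec.rates
    c1, c2 = spec.costs
    budget = spec.budget
    n01, n02 = spec.initial_counts
    endpoint: dict[tuple[int, int], float] = {}

    # depth-first over division sequences; absorption per the overshoot rule
    stack = [(0, 0, budget, 1.0)]
    while stack:
        d1, d2, remaining, prob = stack.pop()
        if not resource_remains(remaining, budget):
            key = (d1, d2)
            endpoint[key] = endpoint.get(key, 0.0) + prob
            continue
        w1 = r1 * (n01 + d1)
        w2 = r2 * (n02 + d2)
        tot = w1 + w2
        if w1 > 0:
            stack.append((d1 + 1, d2, remaining - c1, prob * w1 / tot))
        if w2 > 0:
            stack.append((d1, d2 + 1, remaining - c2, prob * w2 / tot))

    pts = np.array(sorted(endpoint), dtype=np.int64)
    probs = np.array([endpoint[tuple(p)] for p in pts])
    return FinalStateDistribution.from_lattice(spec, pts, probs, method="enumerate")


def forward_dp(spec: DropletSpec, guard: int = DP_GUARD) -> FinalStateDistribution:
    """Exact endpoint distribution by forward lattice dynamic programming.

    Mass is propagated over anti-diagonals d1 + d2 = s in increasing s;
    each active state splits its mass by the rate-weighted next-division
    probability, absorbed states keep theirs. Exact up to float rounding
    (agrees with :func:`enumerate_paths` to ~1e-15 where both run).
    """
    validate_droplet(spec)
    _check_two_types(spec)
    if max_divisions(spec) > guard:
        raise InstanceTooLargeError(
            f"instance-too-large: up to {max_divisions(spec)} divisions exceeds DP guard {guard}"
        )
    r1, r2 = spec.rates
    c1, c2 = spec.costs
    budget = spec.budget
    n01, n02 = spec.initial_counts
    D1 = int(np.ceil(budget / c1))
    D2 = int(np.ceil(budget / c2))

    mass = np.zeros((D1 + 1, D2 + 1))
    mass[0, 0] = 1.0
    for s in range(D1 + D2 + 1):
        d1 = np.arange(max(0, s - D2), min(s, D1) + 1)
        d2 = s - d1
        m = mass[d1, d2]
        live = m > 0
        if not live.any():
            continue
        remaining = budget - (c1 * d1 + c2 * d2)
        act = live & resource_remains(remaining, budget)
        if not act.any():
            continue
        a1, a2 = d1[act], d2[act]
        w1 = r1 * (n01 + a1)
        w2 = r2 * (n02 + a2)
        p1 = w1 / (w1 + w2)
        mass[a1 + 1, a2] += m[act] * p1
        mass[a1, a2 + 1] += m[act] * (1.0 - p1)
        mass[a1, a2] = 0.0

    i, j = np.nonzero(mass)
    pts = np.stack([i, j], axis=1)
    return FinalStateDistribution.from_lattice(spec, pts, mass[i, j], method="dp")
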