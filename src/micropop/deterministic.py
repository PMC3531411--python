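"""Average (deterministic) dynamics of droplet growth.

While resource remains, each type grows exponentially at its own rate
(step-function dependence of the division rate on the substrate):
``n_i(t) = n_i(0) * exp(rate_i * t)``. Growth stops at the time T when the
cumulative cost-weighted growth exhausts the budget,

    sum_i cost_i * (n_i(T) - n_i(0)) = S0.

For a uniform population this gives the linear law
``N_f = N0 + yield * S0``. For two types with rate ratio exactly 2 the
stopping condition is a quadratic in ``x = exp(rate_slow * T)`` and admits
a closed form, from which a small-inoculum expansion shows the correction
to the final size induced by yield variability scales as sqrt(N0), with a
sign set by the rate/yield correlation: tradeoff (r < 1) makes N_f increase
with inoculum size, positive correlation (r > 1) makes it decrease.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .core import (
    DropletSpec,
    NoRootError,
    PreconditionError,
    validate_droplet,
)

_SOLVER_RTOL = 1e-13


@dataclass(frozen=True)
class DeterministicSolution:
    """Stopping time T and final sizes of the average dynamics."""

    stop_time: float
    per_type_final: tuple[float, ...]
    method: str  # numeric | closed_form | expansion

    @property
    def n_final(self) -> float:
        return float(sum(self.per_type_final))


def grow_uniform(n0: float, yield_: float, budget: float, rate: float = 1.0) -> DeterministicSolution:
    """Uniform-population growth: ``N_f = n0 + yield * budget``."""
    if min(n0, yield_, rate) <= 0 or budget < 0:
        raise NoRootError("no-root: parameters must be positive")
    n_final = n0 + yield_ * budget
    stop_time = math.log(n_final / n0) / rate
    return DeterministicSolution(stop_time=stop_time, per_type_final=(n_final,), method="numeric")


def _consumed(spec: DropletSpec, counts0: np.ndarray, T: float) -> float:
    growth = counts0 * (np.exp(spec.rates * T) - 1.0)
    return float(np.dot(spec.costs, growth))


def solve_stopping_time(
    spec: DropletSpec, counts_override: Sequence[float] | None = None
) -> DeterministicSolution:
    """Numerically solve the resource-exhaustion condition for T.

    ``counts_override`` allows real-valued initial splits (the continuum
    approximation uses half/half for a symmetric inoculum even when N0 is
    odd); it defaults to the spec's integer counts.
    """
    validate_droplet(spec)
    counts0 = np.asarray(counts_override if counts_override is not None else spec.counts, dtype=float)
    if counts0.shape != (spec.n_types,) or counts0.sum() <= 0:
        raise NoRootError("no-root: initial split must be non-negative with positive total")
    if spec.budget <= 0:
        raise NoRootError("no-root: budget must be positive")

    f = lambda T: _consumed(spec, counts0, T) - spec.budget
    hi = 1.0 / spec.rates.max()
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:  # unreachable for valid specs: consumption is unbounded in T
            raise NoRootError("no-root: could not bracket the stopping time")
    T = brentq(f, 0.0, hi, rtol=_SOLVER_RTOL, xtol=1e-300)
    finals = counts0 * np.exp(spec.rates * T)
    return DeterministicSolution(stop_time=float(T), per_type_final=tuple(finals), method="numeric")


def _slow_fast(spec: DropletSpec, counts_override=None):
    if spec.n_types != 2:
        raise PreconditionError("precondition-violated: two types required")
    counts0 = np.asarray(counts_override if counts_override is not None else spec.counts, dtype=float)
    order = np.argsort(spec.rates, kind="stable")
    s, f = order
    return (
        spec.rates[s],
        spec.rates[f],
        spec.costs[s],
        spec.costs[f],
        counts0[s],
        counts0[f],
        order,
    )


def closed_form_ratio2(
    spec: DropletSpec, counts_override: Sequence[float] | None = None
) -> DeterministicSolution:
    """Closed-form final size for rate ratio exactly 2.

    With ``x = exp(rate_slow * T)`` the stopping condition is the quadratic

        c_f * a_f * x**2 + c_s * a_s * x - (c_s*a_s + c_f*a_f + S0) = 0,

    whose physical root x > 1 gives the per-type finals ``a_s * x`` and
    ``a_f * x**2``.
    """
    validate_droplet(spec)
    ls, lf, cs, cf, a_s, a_f, order = _slow_fast(spec, counts_override)
    if abs(lf / ls - 2.0) > 1e-12:
        raise PreconditionError(f"precondition-violated: rate ratio must be exactly 2, got {lf / ls}")
    K = cs * a_s + cf * a_f + spec.budget
    if a_f == 0:  # degenerate: only the slow type grows, condition is linear
        x = K / (cs * a_s)
    else:
        x = (-cs * a_s + math.sqrt((cs * a_s) ** 2 + 4.0 * cf * a_f * K)) / (2.0 * cf * a_f)
    finals = np.empty(2)
    finals[order[0]] = a_s * x
    finals[order[1]] = a_f * x * x
    return DeterministicSolution(
        stop_time=math.log(x) / ls, per_type_final=tuple(finals), method="closed_form"
    )


def expansion_small_eps(
    spec: DropletSpec, counts_override: Sequence[float] | None = None
) -> DeterministicSolution:
    """Small-inoculum expansion of the rate-ratio-2 closed form.

    Expanding the quadratic root in the small parameter
    eps ~ inoculum / (budget-supported divisions) gives

        N_f ~ S/c_f + a_f + a_s*c_s/c_f
              + (1 - c_s/c_f) * a_s * [ sqrt(S/(c_f*a_f))
                  * (1 + (c_s*a_s + c_f*a_f)/(2S)) - c_s*a_s/(2*c_f*a_f) ].

    The yield-variability correction is the (1 - c_s/c_f) term: it vanishes
    identically for uniform yield (recovering ``N_f = N0 + y*S``) and its
    leading piece scales as sqrt(N0) for a symmetric inoculum, positive
    under a metabolic tradeoff (c_f > c_s, i.e. r < 1) and negative under
    positive rate/yield correlation.
    """
    validate_droplet(spec)
    ls, lf, cs, cf, a_s, a_f, order = _slow_fast(spec, counts_override)
    if abs(lf / ls - 2.0) > 1e-12:
        raise PreconditionError(f"precondition-violated: rate ratio must be exactly 2, got {lf / ls}")
    if a_f <= 0:
        raise PreconditionError("precondition-violated: expansion needs cells of the fast type")
    S = spec.budget
    K = cs * a_s + cf * a_f + S
    x_approx = math.sqrt(S / (cf * a_f)) * (1.0 + (cs * a_s + cf * a_f) / (2.0 * S)) - cs * a_s / (
        2.0 * cf * a_f
    )
    # N_f = K/c_f + (1 - c_s/c_f) * a_s * x, by eliminating x^2 through the quadratic
    n_final = K / cf + (1.0 - cs / cf) * a_s * x_approx
    finals = np.empty(2)
    finals[order[0]] = a_s * x_approx
    finals[order[1]] = n_final - a_s * x_approx
    return DeterministicSolution(
        stop_time=math.log(max(x_approx, 1.0)) / ls, per_type_final=tuple(finals), method="expansion"
    )


def sweep_inoculum(
    n0_values: Sequence[int],
    budget: float,
    rate_ratio: float,
    yield_ratio: float,
    method: str = "numeric",
) -> list[tuple[int, DeterministicSolution]]:
    """Final size versus inoculum size at fixed budget (half/half split)."""
    from .core import two_type_droplet

    out = []
    solver = {"numeric": solve_stopping_time, "closed_form": closed_form_ratio2, "expansion": expansion_small_eps}[method]
    for n0 in n0_values:
        spec = two_type_droplet(int(n0), budget, rate_ratio=rate_ratio, yield_ratio=yield_ratio)
        out.append((int(n0), solver(spec, counts_override=[n0 / 2.0, n0 / 2.0])))
    return out
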