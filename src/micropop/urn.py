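"""Polya-urn theory of the stopping-line distributions.

For equal rates and equal yields the division sequence maps exactly to
Polya's urn: each drawn ball is returned with one more of its color, so the
number of type-1 divisions out of D is Beta-Binomial(D, a1, a2) — uniform on
{0..D} for the single-cell-per-type inoculum. For unequal rates the ratio
lambda2/lambda1 is approximated by a ratio of integers k2/k1 and each cell
of type i is represented by k_i balls with reinforcement k_i, which keeps
the color-choice odds faithful to the division-rate odds.

After many divisions the composition approaches a limit law whose shape is
independent of the number of divisions but depends on the inoculum: for
equal rates the fraction of type-1 divisions tends to Beta(a1, a2); for
unequal rates the scaling variable

    z = W1 / (W1 + W2**rho),    W_i ~ Gamma(a_i, 1),  rho = lambda1/lambda2

(from the Yule-process limits ``n_i(t) e^{-lambda_i t} -> W_i``) has no
closed-form density but is sampled directly and validated against
jump-chain simulation.

Variable yields tilt the stopping line; the monotone-trajectory argument
maps the variable-yield cumulative law onto the uniform-yield one with an
effective division number, yielding the distribution and moments of final
population size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import betaln, gammaln
from scipy.stats import ks_2samp

from .core import (
    DropletSpec,
    InvalidParameterError,
    OutOfSupportError,
    PreconditionError,
    ToleranceUnreachableError,
)
from .exact import (
    FinalStateDistribution,
    Moments,
    distribution_moments,
    forward_dp,
    max_divisions,
)
from .simulate import run_ensemble


@dataclass(frozen=True)
class UrnSpec:
    """A (generalized) Polya urn.

    ``a1``/``a2`` initial cells of each color, ``D`` draws in total;
    ``reinforcement = (k1, k2)`` balls added per draw of each color, with
    each type-i cell represented by ``k_i`` balls (coprime integers whose
    ratio approximates the division-rate ratio).
    """

    a1: int
    a2: int
    D: int
    reinforcement: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0 or self.a1 + self.a2 < 1:
            raise InvalidParameterError("invalid-parameter: urn needs a1, a2 >= 0 with a1 + a2 >= 1")
        if self.D < 1:
            raise InvalidParameterError("invalid-parameter: D must be >= 1")
        k1, k2 = self.reinforcement
        if k1 < 1 or k2 < 1:
            raise InvalidParameterError("invalid-parameter: reinforcement must be positive integers")
        if math.gcd(int(k1), int(k2)) != 1:
            raise InvalidParameterError("invalid-parameter: reinforcement pair must be coprime")


@dataclass(frozen=True)
class ScaledComposition:
    """Samples of the limiting composition scaling variable z in [0, 1]."""

    z: np.ndarray
    rho: float

    def __post_init__(self) -> None:
        z = np.atleast_1d(np.asarray(self.z, dtype=float))
        if np.any((z < 0) | (z > 1)):
            raise InvalidParameterError("invalid-parameter: z must lie in [0, 1]")
        object.__setattr__(self, "z", z)


def _require_equal_reinforcement(urn: UrnSpec) -> None:
    k1, k2 = urn.reinforcement
    if k1 != k2:
        raise PreconditionError("precondition-violated: Beta-Binomial law requires equal rates (k1 == k2)")


def beta_binomial_pmf(d1: int | np.ndarray, urn: UrnSpec) -> float | np.ndarray:
    """P(d1 type-1 divisions out of D) under the equal-rate Polya urn.

    ``C(D, d1) * B(a1 + d1, a2 + D - d1) / B(a1, a2)``. An empty color
    (a_i = 0) degenerates to a point mass on the other color.
    """
    _require_equal_reinforcement(urn)
    d = np.asarray(d1)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    if np.any((d < 0) | (d > urn.D)):
        raise OutOfSupportError(f"out-of-support: d1 must lie in [0, {urn.D}]")
    if urn.a1 == 0:
        p = (d == 0).astype(float)
    elif urn.a2 == 0:
        p = (d == urn.D).astype(float)
    else:
        logc = gammaln(urn.D + 1) - gammaln(d + 1) - gammaln(urn.D - d + 1)
        p = np.exp(logc + betaln(urn.a1 + d, urn.a2 + urn.D - d) - betaln(urn.a1, urn.a2))
    return float(p[0]) if scalar else p


def beta_binomial_cdf(d1: int, urn: UrnSpec) -> float:
    """P(type-1 divisions <= d1) under the equal-rate Polya urn."""
    if d1 < 0:
        return 0.0
    d1 = min(int(d1), urn.D)
    return float(np.sum(beta_binomial_pmf(np.arange(d1 + 1), urn)))


def composition_cv(urn: UrnSpec) -> tuple[float, float]:
    """(std/mean of d1 at D draws, its D -> infinity limit).

    From the Beta-Binomial moments,
    ``CV(D)^2 = a2 (a1 + a2 + D) / (D a1 (a1 + a2 + 1))``; as D grows this
    decreases monotonically to ``sqrt(a2 / (a1 (a1 + a2 + 1)))``, which for
    a symmetric inoculum a1 = a2 = N0/2 is ``(N0 + 1)^(-1/2)`` — the
    inverse-square-root inoculum scaling of the relative width.
    """
    _require_equal_reinforcement(urn)
    if urn.a1 == 0:
        raise PreconditionError("precondition-violated: CV undefined for zero mean (a1 = 0)")
    a1, a2, D = urn.a1, urn.a2, urn.D
    s = a1 + a2
    mean = D * a1 / s
    var = D * a1 * a2 * (s + D) / (s**2 * (s + 1))
    limit = math.sqrt(a2 / (a1 * (s + 1)))
    return math.sqrt(var) / mean, limit


def rationalize_rate_ratio(ratio: float, tol: float = 1e-6, max_denominator: int = 10**6) -> tuple[int, int]:
    """Smallest coprime (k1, k2) with ``|k2/k1 - ratio| <= tol * ratio``.

    Scans denominators in increasing order (equivalent to walking the
    continued-fraction convergents/semiconvergents), so the first hit is
    the minimal one and automatically in lowest terms.
    """
    if not (ratio > 0 and math.isfinite(ratio)):
        raise InvalidParameterError(f"invalid-parameter: ratio must be positive, got {ratio}")
    if tol <= 0:
        raise InvalidParameterError("invalid-parameter: tol must be positive")
    bound = tol * ratio
    block = 100_000
    for lo in range(1, max_denominator + 1, block):
        q = np.arange(lo, min(lo + block, max_denominator + 1), dtype=np.int64)
        p = np.maximum(np.rint(ratio * q).astype(np.int64), 1)
        ok = np.abs(p / q - ratio) <= bound
        if ok.any():
            i = int(np.argmax(ok))
            return int(q[i]), int(p[i])
    raise ToleranceUnreachableError(
        f"tolerance-unreachable: no denominator <= {max_denominator} approximates {ratio} within {tol}"
    )


def urn_from_rates(a1: int, a2: int, D: int, rate_ratio: float, tol: float = 1e-6) -> UrnSpec:
    """Generalized urn whose reinforcement ratio approximates lambda2/lambda1."""
    k1, k2 = rationalize_rate_ratio(rate_ratio, tol)
    return UrnSpec(a1=a1, a2=a2, D=D, reinforcement=(k1, k2))


def simulate_urn(urn: UrnSpec, seed: int, n_reps: int) -> np.ndarray:
    """Draw-count samples d1 from the generalized urn (D draws each).

    Each type-i cell holds k_i balls and a draw of color i adds k_i balls,
    so color odds stay proportional to ``k_i * (cells of type i)`` — the
    urn is exactly the jump chain with integer rates (k1, k2) run for D
    divisions (unit costs, budget D).
    """
    k1, k2 = urn.reinforcement
    spec = DropletSpec.from_arrays(
        counts=(urn.a1, urn.a2), rates=(float(k1), float(k2)), yields=(1.0, 1.0), budget=float(urn.D)
    )
    ens = run_ensemble(spec, n_reps=n_reps, seed=seed, mode="jump")
    return ens.d_counts[:, 0]


def sample_limit_composition(
    a1: int, a2: int, rho: float, rng: np.random.Generator, size: int = 1
) -> ScaledComposition:
    """Sample the limiting composition variable z = W1 / (W1 + W2**rho).

    ``W_i ~ Gamma(a_i, 1)`` and ``rho = lambda1/lambda2``. For rho = 1 this
    is exactly Beta(a1, a2); for rho != 1 the law has no closed form and is
    validated against jump-chain simulation (KS contract).
    """
    if rho <= 0:
        raise InvalidParameterError(f"invalid-parameter: rho must be positive, got {rho}")
    if a1 < 0 or a2 < 0 or a1 + a2 < 1:
        raise InvalidParameterError("invalid-parameter: need a1, a2 >= 0 with a1 + a2 >= 1")
    w1 = rng.gamma(a1, size=size) if a1 > 0 else np.zeros(size)
    w2 = rng.gamma(a2, size=size) if a2 > 0 else np.zeros(size)
    z = w1 / (w1 + w2**rho)
    return ScaledComposition(z=z, rho=rho)


def simulate_scaled_composition(
    a1: int, a2: int, rho: float, n_divisions: int, seed: int, n_reps: int
) -> np.ndarray:
    """Empirical scaled composition ``n1 / (n1 + n2**rho)`` after a fixed
    number of divisions of the jump chain with rate ratio lambda1/lambda2 = rho."""
    spec = DropletSpec.from_arrays(
        counts=(a1, a2), rates=(rho, 1.0), yields=(1.0, 1.0), budget=float(n_divisions)
    )
    ens = run_ensemble(spec, n_reps=n_reps, seed=seed, mode="jump")
    n1 = ens.d_counts[:, 0] + a1
    n2 = ens.d_counts[:, 1] + a2
    return n1 / (n1 + n2.astype(float) ** rho)


@dataclass
class LimitShapeReport:
    """KS comparison of scaled-composition laws across D and across inocula."""

    rho: float
    alpha: float
    across_D: list[dict] = field(default_factory=list)
    across_inocula: list[dict] = field(default_factory=list)

    @property
    def shape_is_d_independent(self) -> bool:
        return all(rec["pvalue"] > self.alpha for rec in self.across_D)

    @property
    def shape_depends_on_inoculum(self) -> bool:
        return all(rec["pvalue"] < self.alpha for rec in self.across_inocula)


def limit_distribution_independence(
    a1: int,
    a2: int,
    rho: float,
    D_list: Sequence[int],
    alt_inocula: Sequence[tuple[int, int]] = (),
    n_samples: int = 10_000,
    seed: int = 0,
    alpha: float = 0.01,
) -> LimitShapeReport:
    """Check that the scaled-composition law is D-independent but
    inoculum-dependent.

    Pairwise two-sample KS tests across the entries of ``D_list`` (expected
    indistinguishable at level ``alpha``) and, at the largest D, against
    each inoculum in ``alt_inocula`` (expected distinguishable when the
    total inoculum differs by a factor >= 2).
    """
    if len(D_list) < 2:
        raise PreconditionError("precondition-violated: need at least two division counts")
    children = iter(np.random.SeedSequence(seed).generate_state(2 * len(D_list) + len(alt_inocula) + 2))
    samples = {D: simulate_scaled_composition(a1, a2, rho, D, int(next(children)) % 2**31, n_samples) for D in D_list}
    report = LimitShapeReport(rho=rho, alpha=alpha)
    Ds = sorted(D_list)
    for i in range(len(Ds)):
        for j in range(i + 1, len(Ds)):
            res = ks_2samp(samples[Ds[i]], samples[Ds[j]])
            report.across_D.append(
                {"D_a": Ds[i], "D_b": Ds[j], "statistic": float(res.statistic), "pvalue": float(res.pvalue)}
            )
    D_ref = Ds[-1]
    for b1, b2 in alt_inocula:
        alt = simulate_scaled_composition(b1, b2, rho, D_ref, int(next(children)) % 2**31, n_samples)
        res = ks_2samp(samples[D_ref], alt)
        report.across_inocula.append(
            {"inoculum": (b1, b2), "D": D_ref, "statistic": float(res.statistic), "pvalue": float(res.pvalue)}
        )
    return report


# ---------------------------------------------------------------------------
# Variable yields: mapping onto the uniform-yield problem
# ---------------------------------------------------------------------------

def _ceil_tol(x: float) -> int:
    """Ceiling robust to float noise (exact integers stay put)."""
    return int(math.ceil(x - 1e-9))


def effective_divisions(d1: int, spec: DropletSpec) -> int:
    """Effective uniform-yield division number D_eff(d1).

    The variable-yield stopping line passes through ``(d1, d2*)`` with
    ``d2* = (S - c1 d1)/c2``; a monotone lattice trajectory first crosses
    the uniform-yield line through that point when its total division count
    reaches ``ceil(d1 + d2*)``.
    """
    c1, c2 = spec.costs
    d2_star = max((spec.budget - c1 * d1) / c2, 0.0)
    return _ceil_tol(d1 + d2_star)


Backend = Literal["auto", "beta_binomial", "dp"]


def yield_map_cdf(d1: int, spec: DropletSpec, backend: Backend = "auto") -> float:
    """P(D1 <= d1) on the variable-yield stopping line via the uniform map.

    Evaluates the uniform-yield (equal unit cost) problem with
    ``D_eff(d1)`` total divisions. Exact on instances where the final
    division is of the cheaper type (in particular whenever
    cost_1 <= cost_2); otherwise accurate to within one division of lattice
    discretization.
    """
    if spec.n_types != 2:
        raise PreconditionError("precondition-violated: two types required")
    c1, _ = spec.costs
    d_max = int(np.ceil(spec.budget / c1))
    if d1 < 0 or d1 > d_max:
        raise OutOfSupportError(f"out-of-support: d1 must lie in [0, {d_max}]")
    D_eff = effective_divisions(d1, spec)
    if D_eff == 0 or d1 >= D_eff:
        return 1.0
    r1, r2 = spec.rates
    if backend == "auto":
        backend = "beta_binomial" if np.isclose(r1, r2, rtol=1e-12) else "dp"
    if backend == "beta_binomial":
        if not np.isclose(r1, r2, rtol=1e-12):
            raise PreconditionError("precondition-violated: beta_binomial backend needs equal rates")
        urn = UrnSpec(a1=spec.initial_counts[0], a2=spec.initial_counts[1], D=D_eff)
        return beta_binomial_cdf(d1, urn)
    uniform = DropletSpec.from_arrays(
        counts=spec.initial_counts, rates=(r1, r2), yields=(1.0, 1.0), budget=float(D_eff)
    )
    return forward_dp(uniform).cdf("d1", d1)


def final_size_distribution(
    spec: DropletSpec, backend: Literal["dp", "map"] = "dp"
) -> FinalStateDistribution:
    """Distribution of the final population size N_f.

    ``backend="dp"`` marginalizes the exact lattice distribution.
    ``backend="map"`` uses the uniform-yield mapping: P(D1 = d1) from CDF
    differences of :func:`yield_map_cdf` and the stopping-line inversion
    ``N_f(d1) = N_0 + d1 + ceil(d2*(d1))``, accurate to the same
    <= 1-division discretization.
    """
    if spec.n_types != 2:
        raise PreconditionError("precondition-violated: two types required")
    if backend == "dp":
        return forward_dp(spec)
    c1, c2 = spec.costs
    d_max = int(np.ceil(spec.budget / c1))
    cdf_prev = 0.0
    pts, probs = [], []
    for d1 in range(d_max + 1):
        cdf = yield_map_cdf(d1, spec)
        p = cdf - cdf_prev
        cdf_prev = cdf
        if p <= 0:
            continue
        d2_eff = _ceil_tol(max((spec.budget - c1 * d1) / c2, 0.0))
        pts.append((d1, d2_eff))
        probs.append(p)
    return FinalStateDistribution.from_lattice(spec, np.array(pts), np.array(probs), method="map")


def final_size_moments(
    spec: DropletSpec,
    backend: Literal["exact", "limit"] = "exact",
    n_samples: int = 100_000,
    seed: int = 0,
    dp_guard: int = 5_000,
) -> tuple[float, float]:
    """(mean, variance) of the final population size.

    ``backend="exact"`` uses the lattice DP (within its guard).
    ``backend="limit"`` uses the large-division limit: sample the Gamma
    pair ``W_i ~ Gamma(a_i, 1)`` of the Yule limits, invert the stopping
    condition ``sum_i c_i (W_i e^{lambda_i T} - a_i) = S`` for T per sample
    (vectorized bisection) and take moments of ``N_f = sum_i W_i
    e^{lambda_i T}``.
    """
    if backend == "exact":
        if max_divisions(spec) > dp_guard:
            raise PreconditionError(
                "precondition-violated: instance exceeds DP guard; use backend='limit'"
            )
        dist = forward_dp(spec, guard=dp_guard)
        mom = distribution_moments(dist, "n_final")
        return mom.mean, mom.variance
    rng = np.random.Generator(np.random.PCG64(seed))
    a = spec.counts.astype(float)
    lam = spec.rates
    c = spec.costs
    W = np.stack(
        [rng.gamma(ai, size=n_samples) if ai > 0 else np.zeros(n_samples) for ai in a]
    )  # (k, n)
    target = spec.budget + float(np.dot(c, a))

    def consumed(T):  # sum_i c_i W_i exp(lambda_i T), vectorized over samples
        return np.einsum("i,ij->j", c, W * np.exp(lam[:, None] * T[None, :]))

    lo = np.zeros(n_samples)
    hi = np.full(n_samples, 1.0 / lam.max())
    while True:
        need = consumed(hi) < target
        if not need.any():
            break
        hi[need] *= 2.0
    for _ in range(100):  # bisection to ~machine precision on T
        mid = 0.5 * (lo + hi)
        high = consumed(mid) > target
        hi[high] = mid[high]
        lo[~high] = mid[~high]
    T = 0.5 * (lo + hi)
    n_final = (W * np.exp(lam[:, None] * T[None, :])).sum(axis=0)
    return float(n_final.mean()), float(n_final.var(ddof=1))
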