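"""Exact stochastic simulation of droplet growth.

Two equivalent views of the same stochastic process are provided:

* :func:`simulate_gillespie` — the continuous-time birth process: waiting
  time to the next division is exponential with total rate
  ``sum_i rate_i * count_i``, the dividing type is chosen with probability
  proportional to ``rate_i * count_i``.
* :func:`simulate_jump_chain` — the embedded division sequence obtained by
  integrating out the waiting times; approximating divisions as Poisson
  processes, the next division is of type i with probability
  ``rate_i * count_i / sum_j rate_j * count_j`` regardless of when it
  occurs. The event-type sequence is distributed identically in both views.

Growth stops when the resource budget is exhausted. Under the default
"overshoot" rule a division may execute whenever remaining resource is
strictly positive (possibly driving it negative); the alternative rule,
where a division must be fully payable, is available behind
``overshoot=False`` for sensitivity checks.

The event loop dispatches on event kind so that phenotype-switching events
could be added later; only division events are implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core import (
    DropletSpec,
    ExtinctPopulationError,
    InvalidParameterError,
    validate_droplet,
)

# Relative slack distinguishing "resource exhausted" from rounding noise in
# the remaining-resource bookkeeping; both the simulators and the exact
# lattice solvers use the same predicate so their stopping sets agree.
_ACTIVE_RTOL = 1e-12


def resource_remains(remaining: np.ndarray | float, budget: float):
    """True where remaining resource is positive beyond rounding noise."""
    return remaining > budget * _ACTIVE_RTOL


def step_probability(counts: Sequence[int] | np.ndarray, rates: Sequence[float] | np.ndarray) -> np.ndarray:
    """Probability that the next division is of each type.

    ``p_i = rate_i * count_i / sum_j rate_j * count_j``; zero for empty
    types. Raises :class:`ExtinctPopulationError` if all counts are zero.
    """
    counts = np.asarray(counts, dtype=float)
    rates = np.asarray(rates, dtype=float)
    w = counts * rates
    tot = w.sum()
    if tot <= 0:
        raise ExtinctPopulationError("extinct-population: all counts are zero")
    return w / tot


def _pick_type(weights: np.ndarray, u: float) -> int:
    """Inverse-CDF draw; shared by scalar and vectorized paths bit-for-bit."""
    c = np.cumsum(weights)
    return min(int((c <= u * c[-1]).sum()), len(weights) - 1)


@dataclass(frozen=True)
class FinalState:
    """Endpoint of one growth trajectory on the stopping set."""

    d_per_type: tuple[int, ...]
    composition: tuple[int, ...]

    @property
    def n_final(self) -> int:
        return int(sum(self.composition))


@dataclass
class Trajectory:
    """The ordered division history of a single micro-population.

    ``events[j]`` is the type index of the j-th division; ``times`` (present
    only for continuous-time simulation) are the strictly increasing
    division times. ``final_counts[i] = initial_counts[i] + #{events == i}``
    and ``consumed`` is the cost-weighted event tally.
    """

    events: np.ndarray
    initial_counts: tuple[int, ...]
    final_counts: tuple[int, ...]
    consumed: float
    stopped: bool
    times: np.ndarray | None = None

    @property
    def d_per_type(self) -> tuple[int, ...]:
        return tuple(f - i for f, i in zip(self.final_counts, self.initial_counts))

    @property
    def n_final(self) -> int:
        return int(sum(self.final_counts))

    @property
    def stop_time(self) -> float | None:
        if self.times is None or len(self.times) == 0:
            return None
        return float(self.times[-1])

    def final_state(self) -> FinalState:
        return FinalState(d_per_type=self.d_per_type, composition=self.final_counts)


def _simulate(spec: DropletSpec, rng: np.random.Generator, timed: bool, overshoot: bool) -> Trajectory:
    validate_droplet(spec)
    counts = spec.counts.copy()
    rates = spec.rates
    costs = spec.costs
    budget = spec.budget
    remaining = budget
    consumed = 0.0
    events: list[int] = []
    times: list[float] = [] if timed else None  # type: ignore[assignment]
    t = 0.0
    while resource_remains(remaining, budget):
        w = counts * rates
        tot = float(w.sum())
        if tot <= 0:
            raise ExtinctPopulationError("extinct-population: all counts are zero")
        if timed:
            u_wait, u_type = rng.random(2)
            t += -np.log1p(-u_wait) / tot
        else:
            u_type = rng.random()
        typ = _pick_type(w, u_type)
        if not overshoot and costs[typ] > remaining * (1 + _ACTIVE_RTOL):
            break  # strict-payment rule: chosen division cannot be afforded
        counts[typ] += 1
        remaining -= costs[typ]
        consumed += costs[typ]
        events.append(typ)
        if timed:
            times.append(t)
    return Trajectory(
        events=np.asarray(events, dtype=np.int64),
        initial_counts=spec.initial_counts,
        final_counts=tuple(int(c) for c in counts),
        consumed=consumed,
        stopped=True,
        times=np.asarray(times, dtype=float) if timed else None,
    )


def simulate_jump_chain(spec: DropletSpec, rng: np.random.Generator, overshoot: bool = True) -> Trajectory:
    """One realization of the division-sequence random walk (no times)."""
    return _simulate(spec, rng, timed=False, overshoot=overshoot)


def simulate_gillespie(spec: DropletSpec, rng: np.random.Generator, overshoot: bool = True) -> Trajectory:
    """One continuous-time realization of the birth process (with times)."""
    return _simulate(spec, rng, timed=True, overshoot=overshoot)


@dataclass
class EnsembleSummary:
    """Replicate-level results of an ensemble of equally prepared droplets."""

    spec: DropletSpec
    mode: str
    seed: int
    n_reps: int
    d_counts: np.ndarray  # (n_reps, n_types) divisions per type
    n_final: np.ndarray  # (n_reps,)
    consumed: np.ndarray  # (n_reps,)
    stop_times: np.ndarray | None  # (n_reps,) or None in jump mode
    trajectories: list[Trajectory] | None = None

    @property
    def mean_n_final(self) -> float:
        return float(self.n_final.mean())

    @property
    def var_n_final(self) -> float:
        return float(self.n_final.var(ddof=1)) if self.n_reps > 1 else 0.0

    @property
    def std_n_final(self) -> float:
        return float(np.sqrt(self.var_n_final))

    @property
    def final_counts(self) -> np.ndarray:
        return self.d_counts + self.spec.counts[None, :]

    @property
    def mean_composition(self) -> np.ndarray:
        """Mean final cell count per type."""
        return self.final_counts.mean(axis=0)

    def final_state_distribution(self):
        """Empirical distribution over trajectory endpoints (two types)."""
        from .exact import FinalStateDistribution  # local import: layering

        pts, counts = np.unique(self.d_counts, axis=0, return_counts=True)
        probs = counts / counts.sum()
        return FinalStateDistribution.from_lattice(self.spec, pts, probs, method="empirical")

    def to_tsv(self, path) -> None:
        import pandas as pd

        cols = {"rep": np.arange(self.n_reps), "seed": np.full(self.n_reps, self.seed)}
        for i in range(self.spec.n_types):
            cols[f"d_type{i + 1}"] = self.d_counts[:, i]
        cols["n_final"] = self.n_final
        cols["consumed"] = self.consumed
        cols["stop_time"] = self.stop_times if self.stop_times is not None else [""] * self.n_reps
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def run_ensemble(
    spec: DropletSpec,
    n_reps: int,
    seed: int,
    mode: Literal["jump", "gillespie"] = "jump",
    overshoot: bool = True,
    retain_trajectories: bool = False,
    rep_chunk: int = 4096,
    step_block: int = 1024,
) -> EnsembleSummary:
    """Simulate ``n_reps`` independent droplets.

    Each replicate gets its own child random stream spawned from ``seed``
    (SeedSequence), so results are bit-reproducible for a fixed seed, mode
    and replicate count, and identical to running the scalar simulators on
    the corresponding child generators one by one. The stepping itself is
    vectorized across replicates in chunks.
    """
    validate_droplet(spec)
    if n_reps < 1:
        raise InvalidParameterError("invalid-parameter: n_reps must be >= 1")
    timed = mode == "gillespie"
    if mode not in ("jump", "gillespie"):
        raise InvalidParameterError(f"invalid-parameter: unknown mode {mode!r}")

    children = np.random.SeedSequence(seed).spawn(n_reps)

    if retain_trajectories:
        trajs = [
            _simulate(spec, np.random.Generator(np.random.PCG64(c)), timed=timed, overshoot=overshoot)
            for c in children
        ]
        d = np.array([t.d_per_type for t in trajs], dtype=np.int64)
        return EnsembleSummary(
            spec=spec,
            mode=mode,
            seed=seed,
            n_reps=n_reps,
            d_counts=d,
            n_final=d.sum(axis=1) + spec.total_inoculum,
            consumed=np.array([t.consumed for t in trajs]),
            stop_times=np.array([t.stop_time for t in trajs]) if timed else None,
            trajectories=trajs,
        )

    k = spec.n_types
    rates = spec.rates
    costs = spec.costs
    budget = spec.budget
    max_steps = int(np.ceil(budget / costs.min())) + 1

    d_all = np.empty((n_reps, k), dtype=np.int64)
    consumed_all = np.empty(n_reps)
    t_all = np.empty(n_reps) if timed else None

    for lo in range(0, n_reps, rep_chunk):
        hi = min(lo + rep_chunk, n_reps)
        gens = [np.random.Generator(np.random.PCG64(c)) for c in children[lo:hi]]
        m = hi - lo
        counts = np.tile(spec.counts, (m, 1))
        remaining = np.full(m, budget)
        consumed = np.zeros(m)
        d = np.zeros((m, k), dtype=np.int64)
        t = np.zeros(m)
        active = np.ones(m, dtype=bool)
        step = 0
        while active.any() and step < max_steps:
            block = min(step_block, max_steps - step)
            # Per-replicate uniform blocks, consumed in the same order as the
            # scalar simulators draw them (global step index == per-replicate
            # step index, since replicates stop permanently).
            if timed:
                u_blocks = np.stack([g.random((block, 2)) for g in gens])
            else:
                u_blocks = np.stack([g.random(block) for g in gens])
            for j in range(block):
                idx = np.nonzero(active)[0]
                if idx.size == 0:
                    break
                w = counts[idx] * rates[None, :]
                cum = np.cumsum(w, axis=1)
                tot = cum[:, -1]
                if timed:
                    t[idx] += -np.log1p(-u_blocks[idx, j, 0]) / tot
                    u_type = u_blocks[idx, j, 1]
                else:
                    u_type = u_blocks[idx, j]
                typ = np.minimum((cum <= (u_type * tot)[:, None]).sum(axis=1), k - 1)
                if not overshoot:
                    afford = costs[typ] <= remaining[idx] * (1 + _ACTIVE_RTOL)
                    active[idx[~afford]] = False
                    idx, typ = idx[afford], typ[afford]
                    if timed:  # the rejected step's clock advance is void
                        pass
                counts[idx, typ] += 1
                remaining[idx] -= costs[typ]
                consumed[idx] += costs[typ]
                d[idx, typ] += 1
                active[idx] = resource_remains(remaining[idx], budget)
            step += block
        d_all[lo:hi] = d
        consumed_all[lo:hi] = consumed
        if timed:
            t_all[lo:hi] = t

    return EnsembleSummary(
        spec=spec,
        mode=mode,
        seed=seed,
        n_reps=n_reps,
        d_counts=d_all,
        n_final=d_all.sum(axis=1) + spec.total_inoculum,
        consumed=consumed_all,
        stop_times=t_all,
    )
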