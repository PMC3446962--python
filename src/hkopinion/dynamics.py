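"""Synchronous bounded-confidence opinion dynamics.

Every agent *i* holds an opinion ``x_i(t)`` in [0, 1] and a confidence
level ``eps_i``.  At each step, *i*'s neighbour set is

    N_i(t) = { j : |x_j(t) - x_i(t)| <= eps_i }

(inclusive boundary; *i* itself is always a member, at distance 0), and
all agents simultaneously move to a weighted average of their
neighbours' opinions — by default the arithmetic mean, weight
``1/|N_i(t)|``.  With a single shared confidence level this is the
classic Hegselmann-Krause model; with heterogeneous levels the influence
becomes asymmetric: an open-minded agent may listen to a close-minded
one that ignores it.

The update is a convex combination of current opinions, so the opinion
range can only contract, and no randomness enters the dynamics: a run is
a pure function of the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .population import Population

__all__ = [
    "OpinionState",
    "WeightScheme",
    "UniformWeights",
    "RunParams",
    "SimResult",
    "neighbor_set",
    "update_step",
    "has_converged",
    "run_simulation",
]


@dataclass(frozen=True)
class OpinionState:
    """Opinion profile x(t) at a non-negative time step t."""

    t: int
    x: np.ndarray

    def __post_init__(self):
        if self.t < 0:
            raise ValueError("time step must be non-negative")
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 1:
            raise ValueError("opinion profile must be a 1-D vector")
        if np.any(x < 0) or np.any(x > 1):
            raise ValueError("opinions must lie in [0, 1]")
        object.__setattr__(self, "x", x)

    @property
    def n(self) -> int:
        return len(self.x)


class WeightScheme:
    """Positive, row-stochastic weights over each agent's neighbour set.

    Subclasses implement :meth:`weights`, returning strictly positive
    weights over the given neighbour indices (they are normalised to sum
    to 1 by the caller if needed).  The default scheme is uniform.
    """

    def weights(self, i: int, neighbors: np.ndarray, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class UniformWeights(WeightScheme):
    """Arithmetic mean: weight 1/|N_i(t)| for every neighbour."""

    def weights(self, i: int, neighbors: np.ndarray, x: np.ndarray) -> np.ndarray:
        return np.full(len(neighbors), 1.0 / len(neighbors))


@dataclass(frozen=True)
class RunParams:
    """Run-length and recording controls.

    ``t_max`` caps the step count (default 10,000); ``tol`` is the
    convergence tolerance on the maximum per-agent opinion change
    (default 1e-8); ``record_mode`` is ``"final"`` (no trajectory),
    ``"full"``, or a positive integer k to keep every k-th state.
    """

    t_max: int = 10_000
    tol: float = 1e-8
    record_mode: str | int = "final"

    def __post_init__(self):
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        rm = self.record_mode
        if not (rm in ("final", "full") or (isinstance(rm, int) and rm >= 1)):
            raise ValueError(f"record_mode must be 'final', 'full', or a positive int, got {rm!r}")


@dataclass(frozen=True)
class SimResult:
    """Outcome of one run: final profile, convergence info, trajectory."""

    final_state: OpinionState
    converged: bool
    convergence_step: int
    trajectory: tuple[OpinionState, ...] | None
    population: Population


def neighbor_set(state: OpinionState, i: int, eps_i: float) -> np.ndarray:
    """Indices j with |x_j - x_i| <= eps_i; always contains i itself."""
    if not (0 <= i < state.n):
        raise IndexError(f"agent index {i} out of range for n={state.n}")
    if eps_i <= 0:
        raise ValueError("confidence level must be positive")
    return np.flatnonzero(np.abs(state.x - state.x[i]) <= eps_i)


def update_step(
    state: OpinionState,
    epsilon_by_agent: np.ndarray,
    weights: WeightScheme | None = None,
) -> OpinionState:
    """One synchronous update of the whole profile.

    In one opinion dimension each neighbour set is a contiguous window
    of the sorted profile, so the uniform default computes every
    neighbourhood mean from a prefix sum after one sort — O(n log n)
    per step instead of the naive O(n^2) pairwise scan.  The window
    mean is clipped to the window's own [min, max] to keep range
    contraction exact under floating-point prefix-sum rounding.  Any
    non-uniform :class:`WeightScheme` falls back to a per-agent loop.
    New opinions lie within [min x, max x] of the input.
    """
    x = state.x
    eps = np.asarray(epsilon_by_agent, dtype=float)
    if len(eps) != state.n:
        raise ValueError("epsilon vector length does not match profile")
    if np.any(eps <= 0):
        raise ValueError("confidence levels must be positive")
    if weights is None or isinstance(weights, UniformWeights):
        xs = np.sort(x, kind="stable")
        prefix = np.concatenate(([0.0], np.cumsum(xs)))
        lo = np.searchsorted(xs, x - eps, side="left")
        hi = np.searchsorted(xs, x + eps, side="right")
        new_x = (prefix[hi] - prefix[lo]) / (hi - lo)
        np.clip(new_x, xs[lo], xs[hi - 1], out=new_x)
    else:
        adj = np.abs(x[None, :] - x[:, None]) <= eps[:, None]
        new_x = np.empty_like(x)
        for i in range(state.n):
            nbrs = np.flatnonzero(adj[i])
            w = np.asarray(weights.weights(i, nbrs, x), dtype=float)
            if np.any(w <= 0):
                raise ValueError("weights must be strictly positive over the neighbour set")
            new_x[i] = np.dot(w, x[nbrs]) / w.sum()
    return OpinionState(t=state.t + 1, x=new_x)


def has_converged(prev: OpinionState, new: OpinionState, tol: float) -> bool:
    """True iff max_i |x_i(new) - x_i(prev)| < tol (strict)."""
    if prev.n != new.n:
        raise ValueError(f"profiles have different lengths ({prev.n} vs {new.n})")
    return bool(np.max(np.abs(new.x - prev.x)) < tol)


def run_simulation(
    pop: Population,
    params: RunParams = RunParams(),
    weights: WeightScheme | None = None,
) -> SimResult:
    """Iterate the synchronous update from x(0) to stabilisation.

    Stops at the first step whose maximum per-agent change falls below
    ``params.tol``, or at ``t_max`` (then ``converged`` is False — not
    an error).  Deterministic given the population: the dynamics contain
    no randomness.
    """
    state = OpinionState(t=0, x=pop.initial_opinions.copy())
    rm = params.record_mode
    traj: list[OpinionState] | None = None if rm == "final" else [state]
    stride = 1 if rm == "full" else rm

    converged = False
    step = params.t_max
    for t in range(1, params.t_max + 1):
        new = update_step(state, pop.epsilon_by_agent, weights)
        if traj is not None and t % stride == 0:
            traj.append(new)
        done = has_converged(state, new, params.tol)
        state = new
        if done:
            converged = True
            step = t
            break
    if traj is not None and traj[-1].t != state.t:
        traj.append(state)  # thinned runs still record the final profile
    return SimResult(
        final_state=state,
        converged=converged,
        convergence_step=step,
        trajectory=tuple(traj) if traj is not None else None,
        population=pop,
    )
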