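"""Construction of differentiated agent populations.

A population is horizontally differentiated into opinion subgroups: every
agent in subgroup *l* carries the same confidence level ``epsilon_l`` (the
maximum opinion distance it tolerates when selecting whose opinions to
average), and subgroup *l* holds a fraction ``f_l`` of the agents.  With a
single level the model reduces to the classic homogeneous
Hegselmann-Krause setting.

Initial opinions live in the unit interval [0, 1] (0 = absolute reject,
1 = complete accept) and are either drawn i.i.d. uniform on a
sub-interval or supplied explicitly.  Subgroup labels are assigned by a
seeded random permutation, *independently* of the opinion values, so a
close-minded agent is equally likely to sit anywhere in the opinion
spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SubgroupSpec",
    "InitialOpinionSpec",
    "Population",
    "subgroup_sizes",
    "draw_initial_opinions",
    "build_population",
]

_FRACTION_ATOL = 1e-9


@dataclass(frozen=True)
class SubgroupSpec:
    """Ordered confidence levels with population fractions.

    Parameters
    ----------
    levels
        Sequence of ``(epsilon, fraction)`` pairs, epsilons strictly
        increasing, each in (0, 1]; fractions in [0, 1] summing to 1.
    """

    levels: tuple[tuple[float, float], ...]

    def __init__(self, levels: Sequence[Sequence[float]]):
        lv = tuple((float(e), float(f)) for e, f in levels)
        if len(lv) == 0:
            raise ValueError("SubgroupSpec needs at least one level")
        eps = [e for e, _ in lv]
        frs = [f for _, f in lv]
        for e in eps:
            if not (0.0 < e <= 1.0):
                raise ValueError(f"confidence level {e} outside (0, 1]")
        if any(b <= a for a, b in zip(eps, eps[1:])):
            raise ValueError("confidence levels must be strictly increasing")
        for f in frs:
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fraction {f} outside [0, 1]")
        if abs(sum(frs) - 1.0) > _FRACTION_ATOL:
            raise ValueError(f"fractions sum to {sum(frs)!r}, expected 1")
        object.__setattr__(self, "levels", lv)

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([e for e, _ in self.levels])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.levels])

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @classmethod
    def homogeneous(cls, epsilon: float) -> "SubgroupSpec":
        """Single-level spec: the homogeneous HK model."""
        return cls([(epsilon, 1.0)])


@dataclass(frozen=True)
class InitialOpinionSpec:
    """How the initial opinion profile x(0) is produced.

    ``kind`` is ``"uniform"`` (i.i.d. uniform on ``interval``) or
    ``"explicit"`` (``values`` passed through verbatim).  ``seed`` is an
    optional override for the uniform draw; when ``None`` the stream is
    derived from the seed given to :func:`build_population`.
    """

    kind: str = "uniform"
    interval: tuple[float, float] = (0.0, 1.0)
    values: tuple[float, ...] | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("uniform", "explicit"):
            raise ValueError(f"unknown initial-opinion kind {self.kind!r}")
        if self.kind == "uniform":
            a, b = self.interval
            if not (0.0 <= a < b <= 1.0):
                raise ValueError(f"interval {self.interval} must satisfy 0 <= a < b <= 1")
        else:
            if self.values is None:
                raise ValueError("explicit initial opinions require values")
            vals = tuple(float(v) for v in self.values)
            if any(not (0.0 <= v <= 1.0) for v in vals):
                raise ValueError("explicit opinions must lie in [0, 1]")
            object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class Population:
    """A fully-specified agent population: who believes what, how openly.

    Invariants: all vectors have length ``n``;
    ``epsilon_by_agent[i] == spec.epsilons[subgroup_label[i]]``; subgroup
    cardinalities match :func:`subgroup_sizes` exactly.
    """

    n: int
    subgroup_label: np.ndarray
    epsilon_by_agent: np.ndarray
    initial_opinions: np.ndarray
    spec: SubgroupSpec = field(compare=False)

    def __post_init__(self):
        for name in ("subgroup_label", "epsilon_by_agent", "initial_opinions"):
            v = getattr(self, name)
            if len(v) != self.n:
                raise ValueError(f"{name} has length {len(v)}, expected n={self.n}")
        eps = self.spec.epsilons
        if not np.array_equal(eps[self.subgroup_label], self.epsilon_by_agent):
            raise ValueError("epsilon_by_agent inconsistent with subgroup labels")

    def to_tsv(self, path) -> None:
        """Write the population as a TSV table (round-trips bit-exactly).

        Columns: agent_id, subgroup, epsilon, x0.  Floats use ``repr``,
        the shortest representation that round-trips in double precision.
        """
        with open(path, "w") as fh:
            fh.write("agent_id\tsubgroup\tepsilon\tx0\n")
            for i in range(self.n):
                fh.write(
                    f"{i}\t{int(self.subgroup_label[i])}\t"
                    f"{float(self.epsilon_by_agent[i])!r}\t"
                    f"{float(self.initial_opinions[i])!r}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "Population":
        """Reload a population written by :meth:`to_tsv`."""
        labels, eps, x0 = [], [], []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["agent_id", "subgroup", "epsilon", "x0"]:
                raise ValueError(f"unexpected population TSV header {header}")
            for line in fh:
                _, lab, e, x = line.rstrip("\n").split("\t")
                labels.append(int(lab))
                eps.append(float(e))
                x0.append(float(x))
        labels_a = np.array(labels, dtype=np.intp)
        eps_a = np.array(eps)
        n = len(labels)
        level_eps = {}
        for lab, e in zip(labels, eps):
            level_eps.setdefault(lab, e)
        counts = np.bincount(labels_a, minlength=max(level_eps) + 1)
        spec = SubgroupSpec(
            [(level_eps[lab], counts[lab] / n) for lab in sorted(level_eps)]
        )
        return cls(
            n=n,
            subgroup_label=labels_a,
            epsilon_by_agent=eps_a,
            initial_opinions=np.array(x0),
            spec=spec,
        )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def subgroup_sizes(spec: SubgroupSpec, n: int) -> list[int]:
    """Integer subgroup cardinalities for ``n`` agents.

    Each fraction is rounded half-away-from-zero; any discrepancy with
    ``n`` is absorbed by the largest-fraction subgroup.  Deterministic.

    Raises
    ------
    ValueError
        If ``n < 1`` or a subgroup with positive fraction would receive
        no agents (the requested differentiation is infeasible at this
        group size).
    """
    if n < 1:
        raise ValueError(f"group size must be >= 1, got {n}")
    fracs = spec.fractions
    counts = [_round_half_away(f * n) for f in fracs]
    largest = int(np.argmax(fracs))
    counts[largest] += n - sum(counts)
    if counts[largest] < 0:
        raise ValueError(f"rounding made subgroup {largest} negative at n={n}")
    for l, (f, c) in enumerate(zip(fracs, counts)):
        if f > 0 and c == 0:
            raise ValueError(
                f"subgroup {l} (fraction {f}) receives 0 of {n} agents; "
                f"increase n or drop the subgroup"
            )
    return counts


def draw_initial_opinions(
    spec: InitialOpinionSpec,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> np.ndarray:
    """Produce the length-``n`` initial opinion vector for ``spec``.

    For the uniform kind the stream comes from ``spec.seed`` when set,
    otherwise from ``seed``.  Identical seed implies identical vector.
    """
    if spec.kind == "explicit":
        vals = np.asarray(spec.values, dtype=float)
        if len(vals) != n:
            raise ValueError(f"explicit opinions have length {len(vals)}, expected {n}")
        return vals.copy()
    source = spec.seed if spec.seed is not None else seed
    if source is None:
        raise ValueError("uniform initial opinions need a seed")
    rng = source if isinstance(source, np.random.Generator) else np.random.default_rng(source)
    a, b = spec.interval
    return rng.uniform(a, b, size=n)


def build_population(
    n: int,
    spec: SubgroupSpec,
    init: InitialOpinionSpec,
    seed: int | np.random.SeedSequence | None = 0,
) -> Population:
    """Assemble a :class:`Population`: sizes, labels, initial opinions.

    One user seed is split into two independent substreams — one for the
    opinion draw, one for the label permutation — so changing the
    subgroup specification never perturbs a shared initial opinion
    vector, and vice versa.  Labels are shuffled independently of the
    opinion values.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    op_ss, lab_ss = ss.spawn(2)
    counts = subgroup_sizes(spec, n)
    x0 = draw_initial_opinions(init, n, seed=op_ss)
    labels = np.repeat(np.arange(spec.n_levels, dtype=np.intp), counts)
    labels = np.random.default_rng(lab_ss).permutation(labels)
    return Population(
        n=n,
        subgroup_label=labels,
        epsilon_by_agent=spec.epsilons[labels],
        initial_opinions=x0,
        spec=spec,
    )
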