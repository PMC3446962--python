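"""Deterministic toy populations with hand-derived expected outcomes.

Each fixture bundles a small explicit population with the next-step
profile and final cluster count worked out by hand, for use in tests
and documentation:

``hk3``
    Three homogeneous agents at (0.0, 0.1, 0.2) with confidence 0.15.
    Every agent sees its immediate neighbours; one synchronous step of
    neighbourhood means gives (0.05, 0.10, 0.15).

``frozen-pair``
    Two agents at (0.0, 0.05) with confidence levels (0.01, 0.2): the
    close-minded agent hears nobody and stays put, the open-minded one
    averages both opinions and moves to 0.025 — the elementary
    asymmetric-influence motif.  Iterated, the open-minded opinion
    halves every step, so the run stabilises in a single cluster at the
    close-minded agent's position.

``consensus-done``
    Twenty agents all at 0.7: a fixed point, one cluster.

``three-level-20``
    Twenty agents in three confidence levels (0.01, 0.2, 0.45): two
    extremists pinned at 0.0 and 1.0 hear only themselves, and a middle
    block of 18 agents at 0.41, 0.42, …, 0.58 (pairwise distances at
    most 0.17) in which every agent — moderate or open-minded — sees
    exactly the whole block and neither extremist.  One step sends the
    whole block to its mean (0.41 + 0.58)/2 = 0.495, leaving three
    clusters of sizes (1, 18, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import Population, SubgroupSpec

__all__ = ["Fixture", "FIXTURE_NAMES", "make_fixture"]


@dataclass(frozen=True)
class Fixture:
    name: str
    population: Population
    expected_next: np.ndarray      # profile after one synchronous update
    expected_n_clusters: int       # clusters of the stabilised profile


def _pop(spec: SubgroupSpec, labels, x0) -> Population:
    labels = np.asarray(labels, dtype=np.intp)
    return Population(
        n=len(labels),
        subgroup_label=labels,
        epsilon_by_agent=spec.epsilons[labels],
        initial_opinions=np.asarray(x0, dtype=float),
        spec=spec,
    )


def _hk3() -> Fixture:
    spec = SubgroupSpec.homogeneous(0.15)
    return Fixture(
        name="hk3",
        population=_pop(spec, [0, 0, 0], [0.0, 0.1, 0.2]),
        expected_next=np.array([0.05, 0.10, 0.15]),
        expected_n_clusters=1,
    )


def _frozen_pair() -> Fixture:
    spec = SubgroupSpec([(0.01, 0.5), (0.2, 0.5)])
    return Fixture(
        name="frozen-pair",
        population=_pop(spec, [0, 1], [0.0, 0.05]),
        expected_next=np.array([0.0, 0.025]),
        expected_n_clusters=1,
    )


def _consensus_done() -> Fixture:
    spec = SubgroupSpec.homogeneous(0.2)
    x = np.full(20, 0.7)
    return Fixture(
        name="consensus-done",
        population=_pop(spec, np.zeros(20, dtype=int), x),
        expected_next=x.copy(),
        expected_n_clusters=1,
    )


def _three_level_20() -> Fixture:
    spec = SubgroupSpec([(0.01, 0.1), (0.2, 0.7), (0.45, 0.2)])
    # extremists at the ends; middle block 0.41..0.58, open-minded agents
    # planted at 0.50-0.53 (far enough from both ends that eps=0.45 still
    # excludes the extremists)
    x0 = np.concatenate([[0.0], np.arange(0.41, 0.585, 0.01), [1.0]])
    labels = np.array([0] + [1] * 9 + [2] * 4 + [1] * 5 + [0])
    mid_mean = x0[1:-1].mean()  # = 0.495 up to float rounding
    expected = np.concatenate([[0.0], np.full(18, mid_mean), [1.0]])
    return Fixture(
        name="three-level-20",
        population=_pop(spec, labels, x0),
        expected_next=expected,
        expected_n_clusters=3,
    )


_BUILDERS = {
    "hk3": _hk3,
    "frozen-pair": _frozen_pair,
    "consensus-done": _consensus_done,
    "three-level-20": _three_level_20,
}

FIXTURE_NAMES = tuple(_BUILDERS)


def make_fixture(name: str) -> Fixture:
    """Return the named fixture; unknown names are rejected."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}") from None
    return builder()
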