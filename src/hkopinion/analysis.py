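"""Post-processing and experiment harness.

Cluster detection on stabilised opinion profiles, convergence timing,
replicate Monte-Carlo sweeps over the close-minded fraction and the
group size, ordinary-least-squares scaling fits, and a grid-scan
estimator of the critical close-minded fraction below which the group
still reaches consensus.

A *final opinion cluster* is a maximal run of sorted opinions whose
consecutive gaps do not exceed a threshold (default 1e-4 — orders of
magnitude above the convergence tolerance of the dynamics, and far
below the smallest confidence level exercised, 0.01).  Consensus means
exactly one cluster; two is polarization; three or more, fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dynamics import RunParams, SimResult, run_simulation
from .population import InitialOpinionSpec, SubgroupSpec, build_population

__all__ = [
    "ClusterSummary",
    "SweepRecord",
    "LinearFit",
    "ExperimentConfig",
    "NoConsensusRegionError",
    "detect_clusters",
    "stabilization_time",
    "sweep_close_minded_fraction",
    "sweep_group_size",
    "fit_linear_scaling",
    "estimate_critical_fraction",
]

DEFAULT_GAP = 1e-4


class NoConsensusRegionError(ValueError):
    """No grid point reached consensus: the critical fraction is below the grid."""


@dataclass(frozen=True)
class ClusterSummary:
    """Final opinion clusters: how many, where, who."""

    n_clusters: int
    centers: np.ndarray          # mean opinion per cluster, ascending
    sizes: np.ndarray            # members per cluster
    membership: np.ndarray       # agent -> cluster index
    gap: float


@dataclass(frozen=True)
class SweepRecord:
    """Replicate cluster counts at one value of a swept factor."""

    factor_name: str
    factor_value: float
    replicate_seeds: tuple[int, ...]
    counts: tuple[int, ...]

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.counts))

    @property
    def sd_count(self) -> float:
        return float(np.std(self.counts, ddof=1)) if len(self.counts) > 1 else 0.0


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    residual_sd: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class ExperimentConfig:
    """Base configuration shared by the sweep drivers.

    ``fractions`` is the full per-subgroup fraction vector (close,
    moderate, open for the three-level experiments).  The fraction
    sweep varies the first (close-minded) entry, holds the *last*
    (open-minded) entry fixed, and gives the remainder to the middle
    subgroup — the protocol of the fixed-open-fraction experiments.
    """

    n: int = 200
    epsilons: tuple[float, ...] = (0.01, 0.2, 0.45)
    fractions: tuple[float, ...] = (0.05, 0.75, 0.20)
    interval: tuple[float, float] = (0.0, 1.0)
    params: RunParams = field(default_factory=RunParams)
    gap: float = DEFAULT_GAP


def detect_clusters(final_opinions: np.ndarray, gap: float = DEFAULT_GAP) -> ClusterSummary:
    """Group opinions into clusters by single-linkage gap splitting.

    Sort the profile and cut wherever two consecutive opinions are more
    than ``gap`` apart; each maximal run is one cluster.  Chaining is
    transitive: opinions at 0.0 and 0.4 join one cluster through a
    bridge at 0.2 when the gap is 0.25.
    """
    x = np.asarray(final_opinions, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("final opinions must be a non-empty 1-D vector")
    if gap <= 0:
        raise ValueError("gap threshold must be positive")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    breaks = np.flatnonzero(np.diff(xs) > gap)
    cluster_of_sorted = np.zeros(len(x), dtype=np.intp)
    cluster_of_sorted[breaks + 1] = 1
    cluster_of_sorted = np.cumsum(cluster_of_sorted)
    membership = np.empty(len(x), dtype=np.intp)
    membership[order] = cluster_of_sorted
    k = int(cluster_of_sorted[-1]) + 1
    sizes = np.bincount(membership, minlength=k)
    centers = np.array([xs[cluster_of_sorted == c].mean() for c in range(k)])
    return ClusterSummary(
        n_clusters=k, centers=centers, sizes=sizes, membership=membership, gap=gap
    )


def stabilization_time(result: SimResult) -> int:
    """First step at which the stop rule fired, for a converged run."""
    if not result.converged:
        raise ValueError("run did not stabilise within t_max; no stabilisation time")
    return result.convergence_step


def _replicate_seed(base_seed: int, *branch: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=[int(base_seed), *map(int, branch)])


def _run_and_count(
    n: int,
    spec: SubgroupSpec,
    init: InitialOpinionSpec,
    seed: np.random.SeedSequence,
    params: RunParams,
    gap: float,
) -> int:
    pop = build_population(n, spec, init, seed)
    result = run_simulation(pop, params)
    return detect_clusters(result.final_state.x, gap).n_clusters


def sweep_close_minded_fraction(
    base: ExperimentConfig,
    fractions: tuple[float, ...],
    replicates: int = 20,
    base_seed: int = 0,
    shared_initials: bool = True,
) -> list[SweepRecord]:
    """Replicate cluster counts as the close-minded fraction varies.

    For each grid fraction p, the population uses fractions
    ``(p, 1 - p - f_open, f_open)`` with the open fraction taken from
    ``base``.  When ``shared_initials`` is True, replicate r draws the
    same initial opinion vector at every grid point (only the label
    assignment responds to the changed subgroup sizes), mirroring the
    fixed-initial-opinions protocol; otherwise every (fraction,
    replicate) pair gets a fresh draw.
    """
    if len(base.epsilons) != 3 or len(base.fractions) != 3:
        raise ValueError("fraction sweep expects a three-level base configuration")
    f_open = base.fractions[-1]
    init = InitialOpinionSpec(kind="uniform", interval=base.interval)
    records = []
    for fi, p in enumerate(fractions):
        if not (0.0 <= p < 1.0) or p + f_open > 1.0 + 1e-12:
            raise ValueError(f"infeasible close-minded fraction {p} with open fraction {f_open}")
        f_mid = 1.0 - p - f_open
        levels = [(e, f) for e, f in zip(base.epsilons, (p, f_mid, f_open)) if f > 0]
        spec = SubgroupSpec(levels)
        counts, seeds = [], []
        for r in range(replicates):
            seed = _replicate_seed(base_seed, r) if shared_initials else _replicate_seed(base_seed, fi, r)
            seeds.append(r)
            counts.append(_run_and_count(base.n, spec, init, seed, base.params, base.gap))
        records.append(
            SweepRecord(
                factor_name="close_minded_fraction",
                factor_value=float(p),
                replicate_seeds=tuple(seeds),
                counts=tuple(counts),
            )
        )
    return records


def sweep_group_size(
    base: ExperimentConfig,
    sizes: tuple[int, ...],
    replicates: int = 20,
    base_seed: int = 0,
) -> list[SweepRecord]:
    """Replicate cluster counts as the group size varies.

    Every (size, replicate) pair uses a fresh seeded initial opinion
    draw; subgroup fractions come from ``base``.
    """
    spec = SubgroupSpec(list(zip(base.epsilons, base.fractions)))
    init = InitialOpinionSpec(kind="uniform", interval=base.interval)
    records = []
    for si, n in enumerate(sizes):
        if n < spec.n_levels:
            raise ValueError(f"group size {n} smaller than the number of subgroups")
        counts, seeds = [], []
        for r in range(replicates):
            seeds.append(r)
            counts.append(
                _run_and_count(int(n), spec, init, _replicate_seed(base_seed, si, r), base.params, base.gap)
            )
        records.append(
            SweepRecord(
                factor_name="group_size",
                factor_value=float(n),
                replicate_seeds=tuple(seeds),
                counts=tuple(counts),
            )
        )
    return records


def fit_linear_scaling(records: list[SweepRecord]) -> LinearFit:
    """OLS of replicate-mean cluster count on the swept factor value.

    Exact on collinear input (residual_sd = 0).  Requires at least two
    distinct factor values.
    """
    xs = np.array([r.factor_value for r in records], dtype=float)
    ys = np.array([r.mean_count for r in records], dtype=float)
    if len(np.unique(xs)) < 2:
        raise ValueError("linear fit needs at least two distinct factor values")
    res = stats.linregress(xs, ys)
    resid = ys - (res.slope * xs + res.intercept)
    dof = len(xs) - 2
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_sd=residual_sd,
        r_squared=float(res.rvalue**2),
        n_points=len(xs),
    )


def estimate_critical_fraction(
    records: list[SweepRecord], consensus_tol: float = 0.05
) -> float:
    """Largest grid fraction whose mean cluster count is <= 1 + tol.

    A grid scan (resolution-limited by construction): above the
    returned fraction the replicate-mean count exceeds the consensus
    band.  Raises :class:`NoConsensusRegionError` when consensus is
    never reached on the grid.
    """
    ok = [r.factor_value for r in records if r.mean_count <= 1.0 + consensus_tol]
    if not ok:
        raise NoConsensusRegionError(
            "no grid fraction reaches consensus; the critical fraction lies below the grid"
        )
    return float(max(ok))
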