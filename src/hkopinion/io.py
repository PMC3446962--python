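"""Serialisation of simulation and sweep outputs.

All tabular files are TSV/CSV with floats printed via ``repr`` — the
shortest representation that round-trips exactly in double precision —
so written trajectories and profiles reload bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .analysis import ClusterSummary, LinearFit, SweepRecord
from .dynamics import SimResult

__all__ = [
    "write_trajectory_long",
    "write_trajectory_wide",
    "read_trajectory_wide",
    "summary_dict",
    "write_summary_json",
    "write_sweep_csv",
    "write_sweep_aggregate_csv",
    "fit_dict",
    "write_fit_json",
    "cluster_summary_dict",
    "read_opinion_column",
]


def _r(v: float) -> str:
    return repr(float(v))


def write_trajectory_long(result: SimResult, path) -> None:
    """Long-format TSV: one row per (step, agent): step, agent_id, subgroup, opinion."""
    if result.trajectory is None:
        raise ValueError("run was recorded final-only; no trajectory to write")
    labels = result.population.subgroup_label
    with open(path, "w") as fh:
        fh.write("step\tagent_id\tsubgroup\topinion\n")
        for state in result.trajectory:
            for i, xi in enumerate(state.x):
                fh.write(f"{state.t}\t{i}\t{int(labels[i])}\t{_r(xi)}\n")


def write_trajectory_wide(result: SimResult, path) -> None:
    """Wide-format TSV: one row per step, one opinion column per agent."""
    if result.trajectory is None:
        raise ValueError("run was recorded final-only; no trajectory to write")
    n = result.population.n
    with open(path, "w") as fh:
        fh.write("step\t" + "\t".join(f"agent_{i}" for i in range(n)) + "\n")
        for state in result.trajectory:
            fh.write(str(state.t) + "\t" + "\t".join(_r(v) for v in state.x) + "\n")


def read_trajectory_wide(path) -> tuple[np.ndarray, np.ndarray]:
    """Return (steps, profiles) from a wide-format trajectory TSV."""
    steps, rows = [], []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            steps.append(int(parts[0]))
            rows.append([float(v) for v in parts[1:]])
    return np.array(steps), np.array(rows)


def summary_dict(result: SimResult, clusters: ClusterSummary | None = None) -> dict:
    """JSON-ready run summary: convergence info, final profile, parameter echo."""
    pop = result.population
    out = {
        "n": pop.n,
        "levels": [{"epsilon": e, "fraction": f} for e, f in pop.spec.levels],
        "subgroup_sizes": np.bincount(pop.subgroup_label, minlength=pop.spec.n_levels).tolist(),
        "converged": result.converged,
        "convergence_step": result.convergence_step,
        "final_opinions": [float(v) for v in result.final_state.x],
    }
    if clusters is not None:
        out["clusters"] = cluster_summary_dict(clusters)
    return out


def write_summary_json(result: SimResult, path, clusters: ClusterSummary | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(summary_dict(result, clusters), fh, indent=1, sort_keys=True)
        fh.write("\n")


def cluster_summary_dict(cs: ClusterSummary) -> dict:
    return {
        "n_clusters": int(cs.n_clusters),
        "centers": [float(c) for c in cs.centers],
        "sizes": [int(s) for s in cs.sizes],
        "membership": [int(m) for m in cs.membership],
        "gap": float(cs.gap),
    }


def write_sweep_csv(records: list[SweepRecord], path) -> None:
    """Per-replicate CSV: factor_name, factor_value, seed, n_clusters."""
    with open(path, "w") as fh:
        fh.write("factor_name,factor_value,seed,n_clusters\n")
        for rec in records:
            for seed, count in zip(rec.replicate_seeds, rec.counts):
                fh.write(f"{rec.factor_name},{_r(rec.factor_value)},{seed},{count}\n")


def write_sweep_aggregate_csv(records: list[SweepRecord], path) -> None:
    """Aggregated CSV: factor_value, mean_count, sd_count, replicates."""
    with open(path, "w") as fh:
        fh.write("factor_value,mean_count,sd_count,replicates\n")
        for rec in records:
            fh.write(f"{_r(rec.factor_value)},{_r(rec.mean_count)},{_r(rec.sd_count)},{len(rec.counts)}\n")


def fit_dict(fit: LinearFit) -> dict:
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "residual_sd": fit.residual_sd,
        "r_squared": fit.r_squared,
        "n_points": fit.n_points,
    }


def write_fit_json(fit: LinearFit, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_dict(fit), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_opinion_column(path, column: str = "opinion") -> np.ndarray:
    """Read one opinion column from a TSV (e.g. a final-profile table)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if column not in header:
            raise ValueError(f"column {column!r} not found in {Path(path).name} (has {header})")
        idx = header.index(column)
        vals = [float(line.rstrip("\n").split("\t")[idx]) for line in fh if line.strip()]
    if not vals:
        raise ValueError(f"no opinion rows in {Path(path).name}")
    return np.array(vals)
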