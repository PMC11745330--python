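"""Result serialisation: CSV tables plus a JSON run manifest.

All tabular output is plain CSV (header row, UTF-8); the manifest records
the exact configuration, seed, and software version so any run can be
replayed bit-for-bit.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .cells import Population
from .competition import CompetitionResult
from .config import RunConfig
from .evolution import TrajectoryRecord, trajectory_summary


def _package_version() -> str:
    try:
        return version("t6sim")
    except PackageNotFoundError:
        return "unknown"


def population_snapshot(pop: Population) -> pd.DataFrame:
    """Flat per-cell table: pose, size, integrity inputs, life status."""
    data = {
        "id": pop.ids,
        "strain": pop.strain,
        "x": pop.pos[:, 0],
        "y": pop.pos[:, 1],
        "angle": pop.angle,
        "length": pop.length,
        "alive": pop.alive,
        "death_time": pop.death_time,
    }
    for i in range(pop.n_toxins):
        data[f"x_{i + 1}"] = pop.toxins[:, i]
    return pd.DataFrame(data)


def timeseries_frame(results: list[CompetitionResult]) -> pd.DataFrame:
    """Tidy (replicate, step, t, strain, count) long-format time series."""
    rows = []
    for res in results:
        long = res.counts_over_time.copy()
        long["step"] = np.arange(len(long))
        long["t"] = res.times
        long = long.melt(id_vars=["step", "t"], var_name="strain", value_name="count")
        long["replicate"] = res.replicate
        rows.append(long)
    return pd.concat(rows, ignore_index=True)[["replicate", "step", "t", "strain", "count"]]


def write_manifest(directory: Path, config: RunConfig, extra: dict | None = None):
    manifest = {
        "t6sim_version": _package_version(),
        "seed": config.seed,
        "kind": config.kind,
        "config": config.to_mapping(),
    }
    if extra:
        manifest.update(extra)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def write_outputs(result, kind: str, directory: str | Path,
                  config: RunConfig | None = None) -> list[Path]:
    """Serialise a run's results into ``directory``; returns written paths.

    ``kind`` selects the schema: ``compete`` expects a list of
    :class:`CompetitionResult`, ``evolve`` a list of
    :class:`TrajectoryRecord`, ``sweep`` a tidy DataFrame.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {directory}: {exc}") from exc
    written: list[Path] = []

    if kind == "compete":
        results: list[CompetitionResult] = result
        ts = directory / "timeseries.csv"
        timeseries_frame(results).to_csv(ts, index=False)
        written.append(ts)
        summary_rows = []
        for res in results:
            row = {"replicate": res.replicate,
                   "all_targets_extinct": res.all_targets_extinct}
            for label in res.config.labels:
                row[f"initial_{label}"] = res.initial_counts[label]
                row[f"final_{label}"] = res.final_counts[label]
                row[f"extinct_{label}"] = res.extinct[label]
            summary_rows.append(row)
        summ = directory / "summary.csv"
        pd.DataFrame(summary_rows).to_csv(summ, index=False)
        written.append(summ)
        for res in results:
            if res.final_population is not None:
                snap = directory / f"snapshot_rep{res.replicate}.csv"
                population_snapshot(res.final_population).to_csv(snap, index=False)
                written.append(snap)
    elif kind == "evolve":
        records: list[TrajectoryRecord] = result
        frames = []
        for k, rec in enumerate(records):
            f = rec.to_frame()
            f.insert(0, "trajectory", k)
            frames.append(f)
        traj = directory / "trajectories.csv"
        pd.concat(frames, ignore_index=True).to_csv(traj, index=False)
        written.append(traj)
        summ = directory / "trajectory_summary.csv"
        trajectory_summary(records).to_csv(summ, index=False)
        written.append(summ)
    elif kind == "sweep":
        sw = directory / "sweep.csv"
        result.to_csv(sw, index=False)
        written.append(sw)
    else:
        raise ValueError(f"unknown output kind {kind!r}")

    if config is not None:
        write_manifest(directory, config)
        written.append(directory / "manifest.json")
    return written
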