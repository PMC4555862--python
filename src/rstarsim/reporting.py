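"""Configuration files, CSV/JSON output and optional heat-map plots."""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .parameter_space import ParameterSpacePoint
from .sweep import (
    CATEGORIES,
    SimulationConfig,
    SweepResult,
    replicate_seed_sequence,
    summarize_frequencies,
)

__all__ = [
    "load_config",
    "space_to_frame",
    "write_space_csv",
    "write_records_csv",
    "read_records_csv",
    "result_from_records",
    "write_frequency_grids",
    "write_manifest",
    "plot_frequency_grids",
]

logger = logging.getLogger(__name__)

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


def load_config(path: str | Path) -> SimulationConfig:
    """Load a flat key-value (YAML) config file; absent keys take defaults.

    Unknown keys raise (typo guard), as do invalid values and configurations
    whose grid cannot be parameterised (e.g. dilution >= the constant mu).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a flat key-value mapping")
    unknown = sorted(set(data) - _CONFIG_FIELDS)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}; valid keys: {sorted(_CONFIG_FIELDS)}")
    if "initial_sizes" in data:
        data["initial_sizes"] = tuple(data["initial_sizes"])
    config = SimulationConfig(**data)
    config.parameter_space()  # validates mu > D across the whole grid
    return config


def space_to_frame(points: Sequence[ParameterSpacePoint]) -> pd.DataFrame:
    """Parameter space as a tidy table, one row per grid point."""
    rows = []
    for pt in points:
        rows.append(
            {
                "point_index": pt.point_index,
                "rstar_a": pt.pair.rstar_a,
                "rstar_b": pt.pair.rstar_b,
                "mu_a": pt.params.mu_a,
                "mu_b": pt.params.mu_b,
                "k_a": pt.params.k_a,
                "k_b": pt.params.k_b,
                "dilution": pt.params.dilution,
                "inequality": pt.metrics.inequality,
                "more_fit_id": pt.metrics.more_fit_id,
                "regime_label": pt.params.regime_label,
                "varying": pt.params.varying,
            }
        )
    return pd.DataFrame(rows)


def write_space_csv(points: Sequence[ParameterSpacePoint], path: str | Path) -> None:
    space_to_frame(points).to_csv(path, index=False)


def write_records_csv(result: SweepResult, path: str | Path) -> None:
    """Long-format results, one row per replicate, full float precision."""
    result.records.to_csv(path, index=False)


def read_records_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    # NaN -> None for the nullable string column
    df["winner_id"] = df["winner_id"].where(df["winner_id"].notna(), None)
    return df


def result_from_records(records: pd.DataFrame) -> SweepResult:
    """Rebuild a SweepResult from a long-format records table.

    The sweep design (regime, sizes, replication, point count) is inferred
    from the records themselves; simulation-only settings keep defaults.
    """
    first = records.iloc[0]
    config = SimulationConfig(
        regime_label=str(first["regime"]),
        varying=str(first["varying"]),
        dilution=float(first["dilution"]),
        mode=str(first["mode"]),
        initial_sizes=tuple(sorted(records["n0"].unique())),
        n_replicates=int(records["replicate"].max()) + 1,
        n_points=int(records["point_index"].max()),
    )
    return SweepResult(records=records, config=config)


def write_frequency_grids(
    grids: dict[str, pd.DataFrame], out_dir: str | Path, prefix: str = "freq"
) -> list[Path]:
    """One CSV per outcome category: point_index rows, initial-size columns."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for category, grid in grids.items():
        path = out_dir / f"{prefix}_{category}.csv"
        grid.to_csv(path, index_label="point_index")
        paths.append(path)
    return paths


def write_manifest(config: SimulationConfig, path: str | Path) -> dict:
    """JSON manifest: full config echo, version, timestamp and per-treatment
    seed entropy, sufficient to re-run any single replicate in isolation."""
    seeds = []
    for point_index in range(1, config.n_points + 1):
        for n0 in config.initial_sizes:
            ss = replicate_seed_sequence(config, point_index, n0, 0)
            seeds.append(
                {
                    "point_index": point_index,
                    "n0": n0,
                    "entropy_prefix": [int(x) for x in ss.entropy[:-1]],
                    "replicate_entropy_suffix": "replicate index 0..n_replicates-1",
                }
            )
    manifest = {
        "package": "rstarsim",
        "version": __version__,
        "created_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": dataclasses.asdict(config),
        "base_seed": config.base_seed,
        "seed_scheme": (
            "numpy SeedSequence(entropy=(base_seed, regime_code, vary_code, "
            "round(dilution*1e9), point_index, n0, replicate))"
        ),
        "treatment_seeds": seeds,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def plot_frequency_grids(
    grids: dict[str, pd.DataFrame], out_dir: str | Path, fmt: str = "png"
) -> list[Path]:
    """Data-faithful heat maps of the percentage grids (optional; needs
    matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for category in CATEGORIES:
        if category not in grids:
            continue
        grid = grids[category]
        fig, ax = plt.subplots(figsize=(6, 5))
        mesh = ax.pcolormesh(
            range(len(grid.columns)),
            grid.index,
            grid.to_numpy(),
            shading="nearest",
            vmin=0,
            vmax=100,
        )
        ax.set_xticks(range(len(grid.columns)), [str(c) for c in grid.columns])
        ax.set_xlabel("initial population size")
        ax.set_ylabel("parameter-space point index")
        ax.set_title(category.replace("_", " "))
        fig.colorbar(mesh, ax=ax, label="% of replicates")
        path = out_dir / f"grid_{category}.{fmt}"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
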