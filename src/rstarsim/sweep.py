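"""Replicated competition experiment: points x initial sizes x replicates.

Each run is classified at the horizon into one of five mutually exclusive
outcomes: dominance of the more fit or the less fit competitor (only defined
where fitness inequality is nonzero), dominance by either species at fitness
equality, co-persistence of both, or dual extinction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import SystemState, run_trajectory
from .parameter_space import ParameterSpacePoint, build_parameter_space

__all__ = [
    "CATEGORIES",
    "SimulationConfig",
    "Outcome",
    "SweepResult",
    "classify_outcome",
    "replicate_seed_sequence",
    "run_replicates",
    "run_sweep",
    "summarize_frequencies",
]

logger = logging.getLogger(__name__)

CATEGORIES = (
    "more_fit_dominant",
    "less_fit_dominant",
    "co_persistence",
    "dual_extinction",
    "dominance_at_equality",
)

DEFAULT_INITIAL_SIZES = (1, 2, 4, 8, 16, 32, 64, 128, 256, 512)

_REGIME_CODE = {"low_growth": 0, "high_growth": 1}
_VARY_CODE = {"mu": 0, "K": 1}
_MODE_CODE = {"deterministic": 0, "stochastic": 1}


@dataclass(frozen=True)
class SimulationConfig:
    """Complete configuration of one experiment sweep.

    Defaults reproduce the canonical design: 35-point R* grid 1.10-1.78,
    D = 0.1/d, I = 10 umol/L, Q = 1e-6 umol/individual, initial sizes
    1..512 (powers of two), 100 replicates, 20 000 steps.
    """

    regime_label: str = "low_growth"
    varying: str = "mu"
    dilution: float = 0.1
    mode: str = "stochastic"
    horizon: int = 20_000
    initial_sizes: tuple[int, ...] = DEFAULT_INITIAL_SIZES
    n_replicates: int = 100
    base_seed: int = 0
    r_min: float = 1.10
    r_max: float = 1.78
    n_points: int = 35
    inflow: float = 10.0
    initial_resource: float = 10.0
    quota: float = 1e-6

    def __post_init__(self) -> None:
        if self.regime_label not in _REGIME_CODE:
            raise ValueError(f"regime_label: unknown regime {self.regime_label!r}")
        if self.varying not in _VARY_CODE:
            raise ValueError(f"varying: must be 'mu' or 'K', got {self.varying!r}")
        if self.mode not in _MODE_CODE:
            raise ValueError(f"mode: must be 'deterministic' or 'stochastic', got {self.mode!r}")
        for name in ("dilution", "horizon", "n_replicates", "inflow", "quota"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name}: must be positive")
        if self.initial_resource < 0:
            raise ValueError("initial_resource: must be non-negative")
        if self.base_seed < 0:
            raise ValueError("base_seed: must be non-negative")
        if not self.initial_sizes:
            raise ValueError("initial_sizes: must be non-empty")
        if any(int(n) != n or n < 1 for n in self.initial_sizes):
            raise ValueError("initial_sizes: must be positive integers")
        object.__setattr__(self, "initial_sizes", tuple(int(n) for n in self.initial_sizes))
        if self.initial_resource > self.inflow:
            warnings.warn(
                "initial_resource exceeds the inflow concentration; the "
                "resource-bound invariant R(t) <= I assumes R(0) <= I",
                stacklevel=2,
            )

    def parameter_space(self) -> list[ParameterSpacePoint]:
        return build_parameter_space(
            regime_label=self.regime_label,
            varying=self.varying,
            dilution=self.dilution,
            inflow=self.inflow,
            quota=self.quota,
            r_min=self.r_min,
            r_max=self.r_max,
            n_points=self.n_points,
        )

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Outcome:
    """Classification of one finished run."""

    category: str
    winner_id: Optional[str]
    extinction_time_a: Optional[int]
    extinction_time_b: Optional[int]


@dataclass(frozen=True)
class SweepResult:
    """Long-format outcome records (one row per replicate) plus the config."""

    records: pd.DataFrame
    config: SimulationConfig

    def frequencies(self) -> dict[str, pd.DataFrame]:
        return summarize_frequencies(self)


def classify_outcome(final_state: SystemState, point: ParameterSpacePoint) -> Outcome:
    """Five-way outcome classification of a run's final state.

    Dominance is labelled more/less fit by comparing the survivor's R* with
    its competitor's (lower R* = more fit); a sole survivor at the fitness
    equality point is dominance_at_equality regardless of identity.
    """
    alive_a = final_state.n_a > 0
    alive_b = final_state.n_b > 0
    if alive_a and alive_b:
        return Outcome("co_persistence", None, None, None)
    if not alive_a and not alive_b:
        return Outcome("dual_extinction", None, None, None)
    winner = "a" if alive_a else "b"
    more_fit = point.metrics.more_fit_id
    if more_fit == "tie":
        category = "dominance_at_equality"
    elif winner == more_fit:
        category = "more_fit_dominant"
    else:
        category = "less_fit_dominant"
    return Outcome(category, winner, None, None)


def replicate_seed_sequence(
    config: SimulationConfig, point_index: int, n0: int, replicate: int
) -> np.random.SeedSequence:
    """Independent, reproducible seed stream for one replicate.

    The entropy pool mixes the base seed with every treatment coordinate, so
    any single replicate can be re-run in isolation and results do not depend
    on execution order.
    """
    return np.random.SeedSequence(
        entropy=(
            config.base_seed,
            _REGIME_CODE[config.regime_label],
            _VARY_CODE[config.varying],
            int(round(config.dilution * 1e9)),
            point_index,
            n0,
            replicate,
        )
    )


def _run_one(point, n0, config, rng) -> Outcome:
    initial = SystemState(
        n_a=n0, n_b=n0, resource=config.initial_resource, t=0
    )
    res = run_trajectory(
        initial, point.params, horizon=config.horizon, mode=config.mode, rng=rng
    )
    out = classify_outcome(res.final, point)
    return Outcome(
        category=out.category,
        winner_id=out.winner_id,
        extinction_time_a=res.extinction_time_a,
        extinction_time_b=res.extinction_time_b,
    )


def run_replicates(
    point: ParameterSpacePoint, n0: int, config: SimulationConfig
) -> list[Outcome]:
    """Run all replicates of one (point, initial size) treatment.

    Deterministic mode has no randomness, so a single trajectory is run and
    broadcast to ``n_replicates`` identical outcomes.
    """
    if config.mode == "deterministic":
        outcome = _run_one(point, n0, config, rng=None)
        return [outcome] * config.n_replicates
    outcomes = []
    for rep in range(config.n_replicates):
        ss = replicate_seed_sequence(config, point.point_index, n0, rep)
        outcomes.append(_run_one(point, n0, config, np.random.default_rng(ss)))
    return outcomes


def run_sweep(config: SimulationConfig, progress: bool = False) -> SweepResult:
    """Run every (point, initial size, replicate) treatment and collect records."""
    points = config.parameter_space()
    rows = []
    n_treatments = len(points) * len(config.initial_sizes)
    done = 0
    for point in points:
        for n0 in config.initial_sizes:
            outcomes = run_replicates(point, n0, config)
            for rep, out in enumerate(outcomes):
                ss = replicate_seed_sequence(config, point.point_index, n0, rep)
                rows.append(
                    (
                        config.regime_label,
                        config.varying,
                        config.dilution,
                        config.mode,
                        point.point_index,
                        point.inequality,
                        n0,
                        rep,
                        out.category,
                        out.winner_id,
                        out.extinction_time_a,
                        out.extinction_time_b,
                        int(ss.generate_state(1)[0]),
                    )
                )
            done += 1
            if progress:
                logger.info(
                    "treatment %d/%d (point %d, n0 %d) done",
                    done,
                    n_treatments,
                    point.point_index,
                    n0,
                )
    records = pd.DataFrame(
        rows,
        columns=[
            "regime",
            "varying",
            "dilution",
            "mode",
            "point_index",
            "inequality",
            "n0",
            "replicate",
            "category",
            "winner_id",
            "extinction_time_a",
            "extinction_time_b",
            "seed",
        ],
    )
    return SweepResult(records=records, config=config)


def summarize_frequencies(result: SweepResult) -> dict[str, pd.DataFrame]:
    """Per-category percentage grids (point_index rows x initial size columns).

    Grids sum to 100% cell-wise across the five categories.  Raises if any
    (point, n0) treatment is missing replicates.
    """
    records = result.records
    config = result.config
    expected_points = list(range(1, config.n_points + 1))
    expected_sizes = list(config.initial_sizes)
    counts = records.groupby(["point_index", "n0"]).size()
    missing = []
    for pi in expected_points:
        for n0 in expected_sizes:
            have = counts.get((pi, n0), 0)
            if have != config.n_replicates:
                missing.append((pi, n0, int(have)))
    if missing:
        raise ValueError(
            "incomplete sweep; (point_index, n0, n_records) with missing "
            f"replicates (expected {config.n_replicates} each): {missing}"
        )
    grids = {}
    for category in CATEGORIES:
        mask = records["category"] == category
        tab = (
            records[mask]
            .groupby(["point_index", "n0"])
            .size()
            .unstack(fill_value=0)
            .reindex(index=expected_points, columns=expected_sizes, fill_value=0)
        )
        grids[category] = 100.0 * tab / config.n_replicates
    return grids
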