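"""R*-based fitness-inequality parameter space.

Two consumers compete for one resource in an open (chemostat-like) system.
Each consumer is summarised by its break-even resource concentration

    R* = D * K / (mu - D),

the concentration at which Monod growth ``mu * R / (K + R)`` exactly balances
dilution ``D``.  The canonical experiment places the two species on mirrored
linear R* gradients (species A ascending, species B descending, equal slopes)
so that fitness inequality grows symmetrically away from the central grid
point where the two R* values coincide.

Relative fitness of one species is its R* divided by the other's; fitness
inequality is the absolute difference of the two (mutually reciprocal)
relative fitnesses.  The species with the *lower* R* is the more fit one.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RstarPair",
    "FitnessMetrics",
    "RegimeParameters",
    "ParameterSpacePoint",
    "REGIME_HALF_SATURATION",
    "REGIME_MEDIAN_MU",
    "DEFAULT_RSTAR_MIN",
    "DEFAULT_RSTAR_MAX",
    "DEFAULT_N_POINTS",
    "build_rstar_grid",
    "fitness_metrics",
    "rstar_from_params",
    "mu_from_rstar",
    "k_from_rstar",
    "build_parameter_space",
]

#: Half-saturation constant K held fixed per growth regime when mu varies
#: with R* (umol/L).
REGIME_HALF_SATURATION = {"low_growth": 0.072, "high_growth": 4.32}

#: Maximum growth rate mu held fixed per regime when K varies with R* (1/day).
#: These are the mu values realised at the central (fitness-equality) grid
#: point of the canonical D = 0.1 configuration.
REGIME_MEDIAN_MU = {"low_growth": 0.105, "high_growth": 0.4}

DEFAULT_RSTAR_MIN = 1.10
DEFAULT_RSTAR_MAX = 1.78
DEFAULT_N_POINTS = 35

_REGIMES = ("low_growth", "high_growth")
_VARYING = ("mu", "K")


@dataclass(frozen=True)
class RstarPair:
    """R* values (umol/L) of the two species at one grid point (1-based index)."""

    rstar_a: float
    rstar_b: float
    point_index: int

    def __post_init__(self) -> None:
        if self.rstar_a <= 0 or self.rstar_b <= 0:
            raise ValueError("R* values must be positive")


@dataclass(frozen=True)
class FitnessMetrics:
    """Reciprocal relative fitnesses, their absolute difference, and the
    identity of the more fit (lower-R*) species (``"a"``, ``"b"`` or ``"tie"``)."""

    rel_fitness_a: float
    rel_fitness_b: float
    inequality: float
    more_fit_id: str


@dataclass(frozen=True)
class RegimeParameters:
    """Full per-species/system parameter set for one simulation.

    Rates are per day, concentrations umol/L, quotas umol per individual.
    """

    mu_a: float
    mu_b: float
    k_a: float
    k_b: float
    dilution: float
    inflow: float
    quota_a: float
    quota_b: float
    regime_label: str
    varying: str

    def __post_init__(self) -> None:
        if min(self.mu_a, self.mu_b) <= self.dilution:
            raise ValueError(
                "mu must exceed the dilution rate for both species "
                f"(mu=({self.mu_a}, {self.mu_b}), D={self.dilution})"
            )
        if min(self.k_a, self.k_b) <= 0:
            raise ValueError("half-saturation constants must be positive")
        if self.dilution <= 0:
            raise ValueError("dilution rate must be positive")

    @property
    def rstar_a(self) -> float:
        return rstar_from_params(self.mu_a, self.k_a, self.dilution)

    @property
    def rstar_b(self) -> float:
        return rstar_from_params(self.mu_b, self.k_b, self.dilution)


@dataclass(frozen=True)
class ParameterSpacePoint:
    """One grid point: R* pair, derived fitness metrics and full parameters."""

    pair: RstarPair
    metrics: FitnessMetrics
    params: RegimeParameters

    @property
    def point_index(self) -> int:
        return self.pair.point_index

    @property
    def inequality(self) -> float:
        return self.metrics.inequality


def build_rstar_grid(
    r_min: float = DEFAULT_RSTAR_MIN,
    r_max: float = DEFAULT_RSTAR_MAX,
    n_points: int = DEFAULT_N_POINTS,
) -> list[RstarPair]:
    """Build the mirrored linear R* grid.

    Species A ascends ``r_min -> r_max`` over ``n_points`` with constant
    step; species B descends the same values in reverse.  ``n_points`` must
    be odd so that a central point with ``rstar_a == rstar_b`` exists.
    """
    if r_min >= r_max:
        raise ValueError(f"r_min must be < r_max (got {r_min} >= {r_max})")
    if r_min <= 0:
        raise ValueError("r_min must be positive")
    if n_points < 3 or n_points % 2 == 0:
        raise ValueError(
            f"n_points must be odd and >= 3 so an equality point exists "
            f"(got {n_points})"
        )
    step = (r_max - r_min) / (n_points - 1)
    pairs = []
    for i in range(n_points):
        pairs.append(
            RstarPair(
                rstar_a=r_min + i * step,
                rstar_b=r_max - i * step,
                point_index=i + 1,
            )
        )
    # Centre the equality point exactly (guard against float drift).
    mid = n_points // 2
    centre = 0.5 * (r_min + r_max)
    pairs[mid] = RstarPair(rstar_a=centre, rstar_b=centre, point_index=mid + 1)
    return pairs


def fitness_metrics(pair: RstarPair) -> FitnessMetrics:
    """Relative fitnesses and fitness inequality for one R* pair."""
    ra, rb = pair.rstar_a, pair.rstar_b
    if ra <= 0 or rb <= 0:
        raise ValueError("R* values must be positive")
    rel_a = ra / rb
    rel_b = rb / ra
    inequality = abs(rel_a - rel_b)
    if ra < rb:
        more_fit = "a"
    elif rb < ra:
        more_fit = "b"
    else:
        more_fit = "tie"
    return FitnessMetrics(
        rel_fitness_a=rel_a,
        rel_fitness_b=rel_b,
        inequality=inequality,
        more_fit_id=more_fit,
    )


def rstar_from_params(mu: float, k: float, d: float) -> float:
    """Break-even resource concentration R* = d*k/(mu - d)."""
    if d <= 0:
        raise ValueError("dilution rate must be positive")
    if mu <= d:
        raise ValueError(
            f"mu must exceed the dilution rate (mu={mu}, d={d}); "
            "otherwise the species cannot persist at any resource level"
        )
    if k <= 0:
        raise ValueError("half-saturation constant must be positive")
    return d * k / (mu - d)


def mu_from_rstar(rstar: float, k: float, d: float) -> float:
    """Maximum growth rate realising a given R*: mu = d + d*k/rstar."""
    if rstar <= 0 or k <= 0 or d <= 0:
        raise ValueError("rstar, k and d must all be positive")
    return d + d * k / rstar


def k_from_rstar(rstar: float, mu: float, d: float) -> float:
    """Half-saturation constant realising a given R*: k = rstar*(mu - d)/d."""
    if d <= 0:
        raise ValueError("dilution rate must be positive")
    if mu <= d:
        raise ValueError(f"mu must exceed the dilution rate (mu={mu}, d={d})")
    if rstar <= 0:
        raise ValueError("rstar must be positive")
    return rstar * (mu - d) / d


def build_parameter_space(
    regime_label: str,
    varying: str = "mu",
    dilution: float = 0.1,
    inflow: float = 10.0,
    quota: float = 1e-6,
    r_min: float = DEFAULT_RSTAR_MIN,
    r_max: float = DEFAULT_RSTAR_MAX,
    n_points: int = DEFAULT_N_POINTS,
) -> list[ParameterSpacePoint]:
    """Construct the full gradient of parameterised grid points.

    The regime's constant parameter is held fixed (K when varying mu, mu when
    varying K) and the varying parameter is recomputed per species so each
    realises its grid R* at the configured dilution rate.
    """
    if regime_label not in _REGIMES:
        raise ValueError(f"regime_label must be one of {_REGIMES}, got {regime_label!r}")
    if varying not in _VARYING:
        raise ValueError(f"varying must be one of {_VARYING}, got {varying!r}")
    if dilution <= 0:
        raise ValueError("dilution rate must be positive")

    pairs = build_rstar_grid(r_min, r_max, n_points)

    if varying == "K":
        mu_const = REGIME_MEDIAN_MU[regime_label]
        if mu_const <= dilution:
            raise ValueError(
                f"constant mu {mu_const} does not exceed dilution {dilution}; "
                f"all {n_points} grid points are infeasible when varying K"
            )

    points = []
    for pair in pairs:
        if varying == "mu":
            k_const = REGIME_HALF_SATURATION[regime_label]
            mu_a = mu_from_rstar(pair.rstar_a, k_const, dilution)
            mu_b = mu_from_rstar(pair.rstar_b, k_const, dilution)
            k_a = k_b = k_const
        else:
            mu_a = mu_b = REGIME_MEDIAN_MU[regime_label]
            k_a = k_from_rstar(pair.rstar_a, mu_a, dilution)
            k_b = k_from_rstar(pair.rstar_b, mu_b, dilution)
        params = RegimeParameters(
            mu_a=mu_a,
            mu_b=mu_b,
            k_a=k_a,
            k_b=k_b,
            dilution=dilution,
            inflow=inflow,
            quota_a=quota,
            quota_b=quota,
            regime_label=regime_label,
            varying=varying,
        )
        points.append(
            ParameterSpacePoint(pair=pair, metrics=fitness_metrics(pair), params=params)
        )
    return points
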