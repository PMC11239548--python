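"""Harris hawks optimization (HHO) and its logistic-chaotic variant (LC-HHOA).

HHO is a population metaheuristic modelled on cooperative hawk hunting.  A
swarm of candidate solutions ("hawks") pursues the best solution found so far
(the "rabbit").  A per-hawk escape-energy scalar ``E = 2*E0*(1 - t/T)`` decays
over iterations and switches each hawk between global exploration (|E| >= 1)
and four exploitation strategies: soft/hard besiege, each with or without
progressive rapid dives driven by heavy-tailed Levy-flight steps.

The logistic-chaotic variant (``variant="lc_hhoa"``) replaces the hawk's
current-position term inside the plain besiege updates with a point generated
from a logistic chaotic map ``x -> c*x*(1-x)`` at control parameter 4.0 (fully
chaotic regime), and also seeds the initial population from the chaotic
sequence.  Chaotic besiege candidates are accepted greedily so the swarm never
moves to a strictly worse point in those branches.

All operations implement minimization; callers maximizing a score negate it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.special import gamma as _gamma

Objective = Callable[[np.ndarray], float]

#: logistic-map points with degenerate (eventually fixed) orbits at control 4.0
_DEGENERATE = (0.0, 0.25, 0.5, 0.75, 1.0)


class InvalidChaoticState(ValueError):
    """Chaotic value/control outside the valid logistic-map regime."""


@dataclass(frozen=True)
class Bounds:
    """Box constraints [lower, upper] of the search space."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.ndim != 1 or lo.shape != hi.shape:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if not np.all(lo < hi):
            raise ValueError("require lower[i] < upper[i] for all i")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def dim(self) -> int:
        return self.lower.shape[0]

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    @classmethod
    def cube(cls, lower: float, upper: float, dim: int) -> "Bounds":
        return cls(np.full(dim, float(lower)), np.full(dim, float(upper)))


@dataclass(frozen=True)
class ChaoticState:
    """Current point of a logistic chaotic stream x -> control*x*(1-x)."""

    value: float
    control: float = 4.0

    def __post_init__(self):
        if not (0.0 < self.value < 1.0):
            raise InvalidChaoticState(f"chaotic value must lie in (0,1), got {self.value}")
        if self.value in _DEGENERATE:
            raise InvalidChaoticState(f"chaotic value {self.value} sits on a degenerate orbit")
        if not (0.0 < self.control <= 4.0):
            raise InvalidChaoticState(f"control must lie in (0,4], got {self.control}")


def logistic_step(value: float, control: float = 4.0) -> float:
    """One iterate of the logistic map, control*value*(1-value).

    ``value`` must lie in the closed unit interval and ``control`` in (0, 4].
    At control 4.0 the map is fully chaotic and conjugate to the doubling map:
    the n-th iterate of x0 equals sin^2(2^n * arcsin(sqrt(x0))).
    """
    if not (0.0 <= value <= 1.0):
        raise InvalidChaoticState(f"value must lie in [0,1], got {value}")
    if not (0.0 < control <= 4.0):
        raise InvalidChaoticState(f"control must lie in (0,4], got {control}")
    return control * value * (1.0 - value)


def advance_chaos(state: ChaoticState) -> ChaoticState:
    """Advance the chaotic stream one step, nudging off degenerate points.

    Floating-point orbits can land exactly on an absorbing point (0, 1/4, 1/2,
    3/4, 1); a one-ulp-scale inward nudge keeps the stream chaotic while
    remaining deterministic.
    """
    v = logistic_step(state.value, state.control)
    if v in _DEGENERATE:
        v = min(max(v, 1e-12), 1.0 - 1e-12) + 1e-12
    return ChaoticState(value=v, control=state.control)


def chaotic_position(state: ChaoticState, bounds: Bounds) -> tuple[np.ndarray, ChaoticState]:
    """Map the next ``dim`` chaotic iterates affinely into the search box.

    Advances the stream once per coordinate; returns the position together
    with the advanced state.
    """
    values = np.empty(bounds.dim)
    for i in range(bounds.dim):
        state = advance_chaos(state)
        values[i] = state.value
    return bounds.lower + values * bounds.span, state


def escape_energy(e0: float, t: int, max_iterations: int) -> float:
    """Prey escape energy E = E0 * 2 * (1 - t/T); |E| >= 1 triggers exploration."""
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    if not (0 <= t <= max_iterations):
        raise ValueError(f"iteration {t} outside [0, {max_iterations}]")
    return e0 * 2.0 * (1.0 - t / max_iterations)


@dataclass(frozen=True)
class LevyConfig:
    """Mantegna-style Levy flight: step = scale * u * sigma / |v|^(1/beta)."""

    beta: float = 1.5
    scale: float = 0.01

    def __post_init__(self):
        if not (1.0 < self.beta <= 2.0):
            raise ValueError("beta must lie in (1, 2]")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def levy_sigma(beta: float) -> float:
    """Closed-form sigma of the Mantegna construction (~0.6966 at beta=1.5)."""
    num = _gamma(1.0 + beta) * np.sin(np.pi * beta / 2.0)
    den = _gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return float((num / den) ** (1.0 / beta))


def levy_flight(dim: int, config: LevyConfig, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed random step vector used in the rapid-dive strategies."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    sigma = levy_sigma(config.beta)
    u = rng.standard_normal(dim)
    v = rng.standard_normal(dim)
    return config.scale * u * sigma / np.abs(v) ** (1.0 / config.beta)


@dataclass
class HawkSwarm:
    """Optimizer population with the best-so-far ("rabbit") bookkeeping."""

    positions: np.ndarray  # (N, D)
    fitness: np.ndarray  # (N,)
    rabbit_position: np.ndarray  # (D,)
    rabbit_fitness: float
    iteration: int
    max_iterations: int

    @property
    def size(self) -> int:
        return self.positions.shape[0]


def mean_position(swarm: HawkSwarm) -> np.ndarray:
    """Coordinatewise arithmetic mean of the hawk positions."""
    if swarm.size < 1:
        raise ValueError("empty swarm")
    return swarm.positions.mean(axis=0)


def exploration_move(
    index: int, swarm: HawkSwarm, bounds: Bounds, rng: np.random.Generator
) -> np.ndarray:
    """Global perching move: random-hawk-relative or rabbit/mean-relative.

    Draws q, r1..r4 uniform on (0,1).  q >= 0.5 perches relative to a random
    hawk; otherwise relative to the rabbit and the population mean.
    """
    q, r1, r2, r3, r4 = rng.uniform(size=5)
    x = swarm.positions[index]
    if q >= 0.5:
        x_rand = swarm.positions[rng.integers(swarm.size)]
        cand = x_rand - r1 * np.abs(x_rand - 2.0 * r2 * x)
    else:
        x_m = mean_position(swarm)
        cand = (swarm.rabbit_position - x_m) - r3 * (bounds.lower + r4 * bounds.span)
    return bounds.clip(cand)


def soft_besiege(position: np.ndarray, rabbit: np.ndarray, E: float, J: float) -> np.ndarray:
    """Light encirclement for energetic prey (|E| >= 0.5, no dive)."""
    delta = rabbit - position
    return delta - E * np.abs(J * rabbit - position)


def hard_besiege(position: np.ndarray, rabbit: np.ndarray, E: float) -> np.ndarray:
    """Tight encirclement for exhausted prey (|E| < 0.5, no dive)."""
    return rabbit - E * np.abs(rabbit - position)


def _greedy_dive(
    position: np.ndarray,
    y_raw: np.ndarray,
    objective: Objective,
    bounds: Bounds,
    rng: np.random.Generator,
    levy: LevyConfig,
    f_position: Optional[float],
) -> tuple[np.ndarray, Optional[float]]:
    """Greedy Y/Z/keep logic shared by the rapid-dive strategies.

    Returns the chosen position and its fitness (None when the hawk keeps
    its current position, whose fitness the caller already knows).
    """
    y = bounds.clip(y_raw)
    s = rng.uniform(size=bounds.dim)
    z = bounds.clip(y + s * levy_flight(bounds.dim, levy, rng))
    fx = float(objective(position)) if f_position is None else float(f_position)
    fy = float(objective(y))
    if fy < fx:
        return y, fy
    fz = float(objective(z))
    if fz < fx:
        return z, fz
    return position, None


def rapid_dive_soft(
    position: np.ndarray,
    rabbit: np.ndarray,
    E: float,
    J: float,
    objective: Objective,
    bounds: Bounds,
    rng: np.random.Generator,
    levy: LevyConfig = LevyConfig(),
    f_position: Optional[float] = None,
) -> np.ndarray:
    """Soft besiege with progressive rapid dives (|E| >= 0.5, r < 0.5).

    Tries Y = rabbit - E*|J*rabbit - position| then a Levy-perturbed Z;
    keeps the first strict improvement over the current position, else stays.
    """
    y_raw = rabbit - E * np.abs(J * rabbit - position)
    return _greedy_dive(position, y_raw, objective, bounds, rng, levy, f_position)[0]


def rapid_dive_hard(
    position: np.ndarray,
    rabbit: np.ndarray,
    swarm_mean: np.ndarray,
    E: float,
    J: float,
    objective: Objective,
    bounds: Bounds,
    rng: np.random.Generator,
    levy: LevyConfig = LevyConfig(),
    f_position: Optional[float] = None,
) -> np.ndarray:
    """Hard besiege with rapid dives (|E| < 0.5, r < 0.5); Y uses the swarm mean."""
    y_raw = rabbit - E * np.abs(J * rabbit - swarm_mean)
    return _greedy_dive(position, y_raw, objective, bounds, rng, levy, f_position)[0]


@dataclass(frozen=True)
class OptimizerConfig:
    population: int = 20
    max_iterations: int = 100
    variant: str = "hho"  # "hho" | "lc_hhoa"
    seed: int = 0
    levy: LevyConfig = field(default_factory=LevyConfig)
    chaos: ChaoticState = field(default_factory=lambda: ChaoticState(0.7))
    patience: Optional[int] = None  # early stop after this many stagnant iterations

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.variant not in ("hho", "lc_hhoa"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass(frozen=True)
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness after each completed iteration
    evaluations: int


def _check_finite(f: float) -> float:
    if not np.isfinite(f):
        raise FloatingPointError(f"objective returned non-finite value {f}")
    return f


def hho_iteration(
    swarm: HawkSwarm,
    objective: Objective,
    bounds: Bounds,
    config: OptimizerConfig,
    rng: np.random.Generator,
    chaos: Optional[ChaoticState] = None,
    _counter: Optional[list] = None,
) -> HawkSwarm:
    """One synchronous pass over all hawks; mutates and returns the swarm.

    Per hawk: draw E0 ~ U(-1,1), compute E; |E| >= 1 explores, otherwise an
    escape-chance draw r and |E| dispatch one of the four exploitation
    strategies.  When ``chaos`` is given (LC variant) the plain besiege
    updates substitute a chaotic position for the hawk's own and are accepted
    greedily.  The rabbit is updated after every evaluation, so its fitness
    never increases.
    """
    t, T = swarm.iteration, swarm.max_iterations
    counter = _counter if _counter is not None else [0]

    def _eval(x):
        counter[0] += 1
        return _check_finite(float(objective(x)))

    for i in range(swarm.size):
        x = swarm.positions[i]
        e0 = rng.uniform(-1.0, 1.0)
        E = escape_energy(e0, t, T)
        chaotic_candidate = False
        f = None
        if abs(E) >= 1.0:
            cand = exploration_move(i, swarm, bounds, rng)
        else:
            r = rng.uniform()
            J = 2.0 * (1.0 - rng.uniform())
            if r >= 0.5:
                base = x
                if chaos is not None:
                    base, chaos = chaotic_position(chaos, bounds)
                    chaotic_candidate = True
                if abs(E) >= 0.5:
                    cand = soft_besiege(base, swarm.rabbit_position, E, J)
                else:
                    cand = hard_besiege(base, swarm.rabbit_position, E)
                cand = bounds.clip(cand)
            else:
                if abs(E) >= 0.5:
                    y_raw = swarm.rabbit_position - E * np.abs(
                        J * swarm.rabbit_position - x
                    )
                else:
                    y_raw = swarm.rabbit_position - E * np.abs(
                        J * swarm.rabbit_position - mean_position(swarm)
                    )
                cand, f = _greedy_dive(
                    x, y_raw, _eval, bounds, rng, config.levy,
                    f_position=swarm.fitness[i],
                )
                if f is None:  # dive kept the current position
                    continue

        if f is None:
            f = _eval(bounds.clip(cand))
            cand = bounds.clip(cand)
        if f < swarm.rabbit_fitness:
            swarm.rabbit_position = np.array(cand, copy=True)
            swarm.rabbit_fitness = f
        if chaotic_candidate and f >= swarm.fitness[i]:
            # greedy acceptance of chaotic besiege candidates: the rabbit was
            # updated above, but the hawk never moves to a worse point
            continue
        swarm.positions[i] = cand
        swarm.fitness[i] = f

    swarm.iteration += 1
    # stash the advanced chaotic stream for the caller (LC variant)
    swarm._chaos = chaos  # type: ignore[attr-defined]
    return swarm


def lc_hhoa_iteration(
    swarm: HawkSwarm,
    objective: Objective,
    bounds: Bounds,
    config: OptimizerConfig,
    rng: np.random.Generator,
    chaos: ChaoticState,
    _counter: Optional[list] = None,
) -> tuple[HawkSwarm, ChaoticState]:
    """LC-HHOA pass: besiege position terms come from the logistic stream."""
    swarm = hho_iteration(swarm, objective, bounds, config, rng, chaos=chaos, _counter=_counter)
    return swarm, swarm._chaos  # type: ignore[attr-defined]


def _initial_positions(
    config: OptimizerConfig, bounds: Bounds, rng: np.random.Generator
) -> tuple[np.ndarray, ChaoticState]:
    chaos = config.chaos
    if config.variant == "lc_hhoa":
        rows = np.empty((config.population, bounds.dim))
        for i in range(config.population):
            rows[i], chaos = chaotic_position(chaos, bounds)
        return rows, chaos
    return rng.uniform(bounds.lower, bounds.upper, size=(config.population, bounds.dim)), chaos


def optimize(
    objective: Objective, bounds: Bounds, config: OptimizerConfig
) -> OptimizationResult:
    """Run the configured variant for up to ``max_iterations`` iterations.

    The trace records the best-so-far (rabbit) fitness after each completed
    iteration and is therefore non-increasing.  With ``config.patience`` set,
    the loop stops once the rabbit has not strictly improved for that many
    consecutive iterations.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    counter = [0]

    def _eval(x):
        counter[0] += 1
        return _check_finite(float(objective(x)))

    positions, chaos = _initial_positions(config, bounds, rng)
    fitness = np.array([_eval(p) for p in positions])
    best = int(np.argmin(fitness))
    swarm = HawkSwarm(
        positions=positions,
        fitness=fitness,
        rabbit_position=positions[best].copy(),
        rabbit_fitness=float(fitness[best]),
        iteration=0,
        max_iterations=config.max_iterations,
    )

    trace = []
    stagnant = 0
    for _ in range(config.max_iterations):
        previous_best = swarm.rabbit_fitness
        if config.variant == "lc_hhoa":
            swarm, chaos = lc_hhoa_iteration(
                swarm, objective, bounds, config, rng, chaos, _counter=counter
            )
        else:
            swarm = hho_iteration(swarm, objective, bounds, config, rng, _counter=counter)
        trace.append(swarm.rabbit_fitness)
        if swarm.rabbit_fitness < previous_best:
            stagnant = 0
        else:
            stagnant += 1
        if config.patience is not None and stagnant > config.patience:
            break

    return OptimizationResult(
        best_position=swarm.rabbit_position.copy(),
        best_fitness=float(swarm.rabbit_fitness),
        trace=np.array(trace),
        evaluations=counter[0],
    )
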