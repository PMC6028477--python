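"""Real-coded genetic algorithm over the trained response surrogates.

Maximizes a fitness function (normally a trained network's original-scale
prediction) over the box of ion concentrations spanned by the experimental
data.  Individuals are real-valued 5-vectors (mM); selection is
fitness-proportionate (roulette wheel), crossover is an arithmetic blend
applied per pair with the configured probability, mutation perturbs each
gene with Gaussian noise scaled to the box width and clips to bounds, and
one elite individual is carried over each generation so the best fitness
trajectory is non-decreasing.  Study defaults: population 50, 500
generations, crossover rate 0.85, mutation rate 0.1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .media import ION_ORDER, IonProfile, load_reference_table

__all__ = [
    "GAConfig",
    "SearchBounds",
    "OptimizationResult",
    "roulette_select",
    "crossover",
    "mutate",
    "optimize",
]

#: Relative floor used when shifting non-positive fitnesses for roulette.
_FITNESS_FLOOR = 1e-6


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    generations: int = 500
    crossover_rate: float = 0.85
    mutation_rate: float = 0.1
    selection: str = "roulette_wheel"
    elitism_count: int = 1
    mutation_scale: float = 0.1  # Gaussian SD as a fraction of box width
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for name in ("crossover_rate", "mutation_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.selection != "roulette_wheel":
            raise ValueError(f"unsupported selection {self.selection!r}")


@dataclass(frozen=True)
class SearchBounds:
    """Per-ion lower/upper bounds (mM) of the search box."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or np.any(lower >= upper):
            raise ValueError("bounds must satisfy lower < upper elementwise")

    @property
    def widths(self) -> np.ndarray:
        return self.upper - self.lower

    @classmethod
    def from_reference(cls) -> "SearchBounds":
        """Box spanned by the 36 experimental media (the dataset range)."""
        table = load_reference_table()
        lo = np.array([table[f"{ion}_mm"].min() for ion in ION_ORDER])
        hi = np.array([table[f"{ion}_mm"].max() for ion in ION_ORDER])
        return cls(lo, hi)

    @classmethod
    def from_array(cls, bounds: np.ndarray) -> "SearchBounds":
        bounds = np.asarray(bounds, dtype=float)
        return cls(bounds[:, 0], bounds[:, 1])

    def contains(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return np.all((X >= self.lower) & (X <= self.upper), axis=1)

    def clip(self, X: np.ndarray) -> np.ndarray:
        return np.clip(X, self.lower, self.upper)


def roulette_select(fitnesses: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``k`` indices with probability proportional to fitness.

    Positive fitnesses are used as-is; if any fitness is <= 0, all are
    shifted so the minimum maps to a small positive floor.  All-equal
    fitnesses degrade to uniform selection.
    """
    f = np.asarray(fitnesses, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    finite = np.isfinite(f)
    if not finite.any():
        raise ValueError("no finite fitness to select from")
    fmin, fmax = f[finite].min(), f[finite].max()
    if fmax == fmin:
        probs = np.where(finite, 1.0, 0.0)
    else:
        floor = _FITNESS_FLOOR * (fmax - fmin)
        shifted = f - fmin + floor if fmin <= 0 else f.copy()
        shifted[~finite] = floor if fmin <= 0 else _FITNESS_FLOOR * fmax
        probs = shifted
    probs = probs / probs.sum()
    return rng.choice(len(f), size=k, p=probs)


def crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic-blend crossover, applied to the pair with probability ``rate``.

    With blend weight α ~ Uniform(0,1): child1 = αa + (1−α)b and child2 the
    complement; convexity keeps offspring inside any box containing both
    parents.  Otherwise the parents are copied unchanged.
    """
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    if rng.random() >= rate:
        return a.copy(), b.copy()
    alpha = rng.random()
    return alpha * a + (1 - alpha) * b, (1 - alpha) * a + alpha * b


def mutate(
    individual: np.ndarray,
    rate: float,
    scale: float,
    bounds: SearchBounds,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-gene Gaussian mutation (SD = scale × box width), clipped to bounds."""
    x = np.array(individual, dtype=float)
    mask = rng.random(x.shape) < rate
    noise = rng.normal(0.0, scale * bounds.widths, size=x.shape)
    x[mask] += noise[mask]
    return bounds.clip(x)


@dataclass
class OptimizationResult:
    """Best individual found, its predicted response, and the run record.

    ``best_ions`` is an :class:`~rootmedia.media.IonProfile` for the usual
    five-gene ion search; for generic benchmark boxes of another dimension it
    is a plain array.  ``best_vector`` is always an array.
    """

    best_ions: "IonProfile | np.ndarray"
    predicted_response: float
    trajectory: list[float] = field(repr=False)
    config: GAConfig = field(default_factory=GAConfig)
    seed: int = 0
    n_flagged_candidates: int = 0

    @property
    def best_vector(self) -> np.ndarray:
        if isinstance(self.best_ions, IonProfile):
            return self.best_ions.as_array()
        return np.asarray(self.best_ions, dtype=float)

    def to_dict(self) -> dict:
        if isinstance(self.best_ions, IonProfile):
            best = {ion: getattr(self.best_ions, ion) for ion in ION_ORDER}
        else:
            best = list(map(float, self.best_ions))
        return {
            "best_ions_mM": best,
            "predicted_response": self.predicted_response,
            "seed": self.seed,
            "n_flagged_candidates": self.n_flagged_candidates,
            "config": {
                "population_size": self.config.population_size,
                "generations": self.config.generations,
                "crossover_rate": self.config.crossover_rate,
                "mutation_rate": self.config.mutation_rate,
                "selection": self.config.selection,
                "elitism_count": self.config.elitism_count,
                "mutation_scale": self.config.mutation_scale,
            },
            "trajectory": self.trajectory,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def optimize(
    fitness: Callable[[np.ndarray], np.ndarray],
    bounds: SearchBounds,
    config: GAConfig | None = None,
) -> OptimizationResult:
    """Maximize ``fitness`` over the box with the generational GA.

    ``fitness`` maps an (n, 5) array of candidate ion profiles (mM) to n
    values on the response's original scale (e.g. a
    :class:`~rootmedia.ann.ResponseModel`'s ``predict``).  Non-finite
    candidate fitnesses are floored to the population minimum and counted in
    ``n_flagged_candidates``.  Deterministic given ``config.seed``.
    """
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    n_genes = bounds.lower.size

    population = bounds.lower + rng.random((config.population_size, n_genes)) * bounds.widths
    best_x: np.ndarray | None = None
    best_f = -np.inf
    trajectory: list[float] = []
    n_flagged = 0

    for _ in range(config.generations):
        f = np.asarray(fitness(population), dtype=float).ravel()
        bad = ~np.isfinite(f)
        if bad.any():
            n_flagged += int(bad.sum())
            floor = f[~bad].min() if (~bad).any() else 0.0
            f[bad] = floor
        gen_best = int(np.argmax(f))
        if f[gen_best] > best_f:
            best_f = float(f[gen_best])
            best_x = population[gen_best].copy()
        trajectory.append(best_f)

        elite_idx = np.argsort(f)[::-1][: config.elitism_count]
        next_pop = [population[i].copy() for i in elite_idx]
        while len(next_pop) < config.population_size:
            ia, ib = roulette_select(f, 2, rng)
            child_a, child_b = crossover(population[ia], population[ib], config.crossover_rate, rng)
            next_pop.append(mutate(child_a, config.mutation_rate, config.mutation_scale, bounds, rng))
            if len(next_pop) < config.population_size:
                next_pop.append(mutate(child_b, config.mutation_rate, config.mutation_scale, bounds, rng))
        population = np.array(next_pop)

    assert best_x is not None
    best = bounds.clip(best_x)
    return OptimizationResult(
        best_ions=IonProfile.from_array(best) if best.size == len(ION_ORDER) else best,
        predicted_response=best_f,
        trajectory=trajectory,
        config=config,
        seed=config.seed,
        n_flagged_candidates=n_flagged,
    )
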