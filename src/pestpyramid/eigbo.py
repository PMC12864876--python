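"""Gooseneck-barnacle population optimizer with fitness-driven random number.

The baseline algorithm (GBOA) updates each population member by an
exploitation move around the best position found so far ("the water region"):

    x_new = o^t * (x_j - x_i) * cos(2*pi*h) + x_best      (componentwise)

where ``x_j`` is a random distinct partner, ``o^t`` a geometric step
contraction (``o`` < 1, ``t`` the iteration index) that anneals the
exploitation radius, and ``h`` is drawn uniformly from [-1, 1]. The EIGBO-RE
variant replaces the uniform draw by a deterministic fitness ratio computed
from the population's fitness statistics:

    h = Currentfit^2 / (Worstfit^2 + Bestfit + Currentfit^2 - Meanfit)

which couples the step geometry to how good the member currently is, damping
the premature convergence a blind random number can cause. An exploration
phase (uniform resampling within bounds, probability decaying linearly over
iterations) and elitism on the best member complete the loop.

The default search space is the 4-gene chromosome tuned in this package:
FPN hidden width and learning-rate gene, LSTM hidden width and learning-rate
gene, with ranges [5, 255] (integers) and [0.01, 0.99] (reals). The training
objective is JK = 1/accuracy + 1/IoU, minimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Gene", "SearchSpace", "Candidate", "FitnessSummary", "OptimizerTrace",
           "objective_jk", "compute_h", "gboa_move", "explore_move", "optimize",
           "default_search_space", "tune_pipeline"]

PENALTY = 1e6


@dataclass(frozen=True)
class Gene:
    name: str
    kind: str                 # "integer" | "real"
    lower: float
    upper: float

    def __post_init__(self):
        if self.kind not in ("integer", "real"):
            raise ValueError("gene kind must be 'integer' or 'real'")
        if not self.lower < self.upper:
            raise ValueError(f"gene {self.name}: lower must be < upper")


@dataclass(frozen=True)
class SearchSpace:
    genes: tuple[Gene, ...]

    @property
    def dim(self) -> int:
        return len(self.genes)

    def clip(self, x: np.ndarray) -> np.ndarray:
        lo = np.array([g.lower for g in self.genes])
        hi = np.array([g.upper for g in self.genes])
        return np.clip(x, lo, hi)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([rng.uniform(g.lower, g.upper) for g in self.genes])

    def materialize(self, x: np.ndarray) -> dict:
        """Round integer genes half-up; reals pass through."""
        out = {}
        for g, v in zip(self.genes, x):
            out[g.name] = int(np.floor(v + 0.5)) if g.kind == "integer" else float(v)
        return out


def default_search_space() -> SearchSpace:
    """The 4-gene chromosome: hidden widths and learning-rate genes."""
    return SearchSpace(genes=(
        Gene("fpn_hidden", "integer", 5, 255),
        Gene("fpn_lr", "real", 0.01, 0.99),
        Gene("lstm_hidden", "integer", 5, 255),
        Gene("lstm_lr", "real", 0.01, 0.99),
    ))


@dataclass
class Candidate:
    position: np.ndarray
    fitness: float | None = None


@dataclass(frozen=True)
class FitnessSummary:
    current: float
    best: float
    worst: float
    mean: float
    h: float


@dataclass
class OptimizerTrace:
    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_position: list[np.ndarray] = field(default_factory=list)
    h_values: list[list[float]] = field(default_factory=list)


# -- primitive operations -----------------------------------------------------

def objective_jk(accuracy: float, iou: float) -> float:
    """JK = 1/accuracy + 1/IoU (minimized); degenerate inputs hit the penalty cap."""
    if accuracy <= 1e-9 or iou <= 1e-9:
        return PENALTY
    return 1.0 / accuracy + 1.0 / iou


def compute_h(current: float, best: float, worst: float, mean: float) -> float:
    """Fitness-driven replacement for the uniform random number.

    h = current^2 / (worst^2 + best + current^2 - mean); the all-equal fixed
    point is 0.5 (returned exactly, bypassing roundoff), which is also the
    fallback when the denominator vanishes.
    """
    if current == best == worst == mean:
        return 0.5
    den = worst * worst + best + current * current - mean
    if den <= 1e-12:          # vanishing or negative denominator: fall back
        return 0.5
    return current * current / den


def gboa_move(x_i: np.ndarray, x_j: np.ndarray, water: np.ndarray,
              h: float, space: SearchSpace, scale: float = 1.0) -> np.ndarray:
    """Exploitation move: scaled inter-parent span * cos(2*pi*h) + attractor.

    The span is the signed difference x_j - x_i: with a scalar cos factor a
    folded (absolute) span would confine every step to the all-positive
    diagonal orthant around the attractor, which cripples the search in
    dimension > 1. ``scale`` is the annealing factor o^t supplied by the
    optimizer loop.
    """
    s = np.asarray(x_j, float) - np.asarray(x_i, float)
    return space.clip(scale * s * np.cos(2 * np.pi * h) + np.asarray(water, float))


def explore_move(space: SearchSpace, rng: np.random.Generator) -> np.ndarray:
    """Exploration: uniform resample of every gene within its bounds."""
    return space.sample(rng)


# -- main loop ----------------------------------------------------------------

def optimize(eval_fn, space: SearchSpace, population: int = 10,
             iterations: int = 50, variant: str = "eigbo_re",
             explore_prob: tuple[float, float] = (0.25, 0.05),
             contraction: float = 0.94,
             seed: int = 0) -> tuple[Candidate, OptimizerTrace]:
    """Minimize ``eval_fn(position) -> fitness`` over ``space``.

    ``variant`` selects how the move's random number h is produced: "gboa"
    draws h ~ U(-1, 1); "eigbo_re" computes it from the member's fitness via
    :func:`compute_h`. The two variants consume identical random streams apart
    from the h draws, so seeded runs are directly comparable. ``contraction``
    is the base of the geometric step-annealing factor o^t. The best member
    is preserved verbatim each iteration (elitism) and the best-so-far fitness
    is therefore non-increasing along the trace.
    """
    if population < 2:
        raise ValueError("population must be >= 2")
    if variant not in ("gboa", "eigbo_re"):
        raise ValueError("variant must be 'gboa' or 'eigbo_re'")
    ss = np.random.SeedSequence((seed, 7))
    rng_main, rng_h = [np.random.default_rng(s) for s in ss.spawn(2)]

    def evaluate(pos: np.ndarray) -> float:
        try:
            f = float(eval_fn(pos))
        except Exception:
            return PENALTY
        return f if np.isfinite(f) else PENALTY

    pop = [Candidate(space.sample(rng_main)) for _ in range(population)]
    for c in pop:
        c.fitness = evaluate(c.position)
    trace = OptimizerTrace()
    best = min(pop, key=lambda c: c.fitness)
    best = Candidate(best.position.copy(), best.fitness)

    for it in range(iterations):
        fits = np.array([c.fitness for c in pop])
        f_best, f_worst, f_mean = fits.min(), fits.max(), fits.mean()
        if f_best < best.fitness:
            i = int(fits.argmin())
            best = Candidate(pop[i].position.copy(), float(fits[i]))
        trace.best_fitness.append(best.fitness)
        trace.mean_fitness.append(float(f_mean))
        trace.best_position.append(best.position.copy())

        frac = it / max(1, iterations - 1)
        p_explore = explore_prob[0] + frac * (explore_prob[1] - explore_prob[0])
        scale = contraction ** it
        hs: list[float] = []
        new_pop: list[Candidate] = []
        for i, c in enumerate(pop):
            do_explore = rng_main.uniform() < p_explore
            j = int(rng_main.integers(population - 1))
            j = j if j < i else j + 1              # random distinct partner
            if do_explore:
                pos = explore_move(space, rng_main)
                hs.append(np.nan)
            else:
                if variant == "gboa":
                    h = float(rng_h.uniform(-1.0, 1.0))
                else:
                    h = compute_h(c.fitness, float(f_best), float(f_worst),
                                  float(f_mean))
                hs.append(h)
                pos = gboa_move(c.position, pop[j].position, best.position,
                                h, space, scale=scale)
            new_pop.append(Candidate(pos, evaluate(pos)))
        trace.h_values.append(hs)
        # elitism: the incumbent replaces the worst of the new population
        worst_i = int(np.argmax([c.fitness for c in new_pop]))
        new_pop[worst_i] = Candidate(best.position.copy(), best.fitness)
        pop = new_pop

    fits = np.array([c.fitness for c in pop])
    if fits.min() < best.fitness:
        i = int(fits.argmin())
        best = Candidate(pop[i].position.copy(), float(fits[i]))
    trace.best_fitness.append(best.fitness)
    trace.mean_fitness.append(float(fits.mean()))
    trace.best_position.append(best.position.copy())
    return best, trace


# -- pipeline tuning objective ------------------------------------------------

def tune_pipeline(split, *, n_classes: int = 3, population: int = 10,
                  iterations: int = 50, variant: str = "eigbo_re",
                  detector_epochs: int = 8, classifier_epochs: int = 12,
                  max_train_scenes: int = 60, max_val_scenes: int = 20,
                  seed: int = 0) -> tuple[dict, OptimizerTrace]:
    """Tune the 4-gene chromosome on a scaled-down train/validation run.

    Each candidate trains the detector and classifier with its genes on a
    subset of the train split, then scores classification accuracy and
    count-based detection IoU on a validation slice; the fitness is
    JK = 1/accuracy + 1/IoU. Returns the best materialized genes and the trace.
    """
    from .pipeline import evaluate_genes   # late import to avoid a cycle

    space = default_search_space()

    def eval_fn(position: np.ndarray) -> float:
        genes = space.materialize(position)
        acc, iou = evaluate_genes(
            split, genes, n_classes=n_classes,
            detector_epochs=detector_epochs, classifier_epochs=classifier_epochs,
            max_train_scenes=max_train_scenes, max_val_scenes=max_val_scenes,
            seed=seed)
        return objective_jk(acc, iou)

    best, trace = optimize(eval_fn, space, population=population,
                           iterations=iterations, variant=variant, seed=seed)
    return space.materialize(best.position), trace
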