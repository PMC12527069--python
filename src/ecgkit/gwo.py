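"""Grey Wolf Optimizer for hyperparameter search.

The GWO is a population metaheuristic in which the three best candidates —
alpha, beta, delta — steer the rest of the pack.  With ``X`` a wolf's
position and ``X_l`` a leader's position, one update draws fresh uniform
``r1, r2`` per leader and dimension and computes

    A = 2*a*r1 - a,   C = 2*r2,
    D = |C * X_l - X|,
    X_k = X_l - A * D           for each leader k in {alpha, beta, delta},
    X(t+1) = (X_1 + X_2 + X_3) / 3,

clipped to the search bounds.  The control scalar ``a`` decreases linearly
from 2 to 0 over the iterations (``a(t) = 2 * (1 - t / n_iters)``), moving
the pack from exploration (|A| can exceed 1) to exploitation.

For model tuning, positions live in a continuous internal space; integer
dimensions are decoded by clip-then-round (half up).  The fitness of a
candidate hyperparameter set is the validation accuracy of a hybrid
CNN-LSTM trained under a reduced epoch budget; :class:`GreyWolfTuner`
wraps the search in the model/results convention and can retrain the best
configuration at full budget.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._exceptions import ConfigurationError, ValidationError
from .io import BeatDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Search space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dimension:
    name: str
    lower: float
    upper: float
    kind: str = "continuous"  # "integer" | "continuous"

    def __post_init__(self):
        if self.lower >= self.upper:
            raise ValidationError(
                f"dimension {self.name!r}: lower {self.lower} >= upper {self.upper}")
        if self.kind not in ("integer", "continuous"):
            raise ValidationError(f"dimension {self.name!r}: kind {self.kind!r}")


@dataclass(frozen=True)
class SearchSpace:
    dimensions: tuple[Dimension, ...]

    def __post_init__(self):
        names = [d.name for d in self.dimensions]
        if len(set(names)) != len(names):
            raise ValidationError("dimension names must be unique")

    def __len__(self):
        return len(self.dimensions)

    @property
    def names(self):
        return tuple(d.name for d in self.dimensions)

    @property
    def lower(self) -> np.ndarray:
        return np.array([d.lower for d in self.dimensions])

    @property
    def upper(self) -> np.ndarray:
        return np.array([d.upper for d in self.dimensions])

    def clip(self, coords: np.ndarray) -> np.ndarray:
        return np.clip(coords, self.lower, self.upper)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper)


#: The standard hyperparameter ranges for hybrid-model tuning.
DEFAULT_SPACE = SearchSpace((
    Dimension("n_filters", 8, 320, "integer"),
    Dimension("kernel_size", 3, 7, "integer"),
    Dimension("stride", 2, 8, "integer"),
    Dimension("lstm_units", 20, 256, "integer"),
    Dimension("dropout", 0.001, 0.6, "continuous"),
))

#: Batch sizes selectable by the extended space's integer index dimension.
BATCH_CHOICES = (16, 20, 32)


def extended_space() -> SearchSpace:
    """Default space plus learning rate (log-uniform) and batch size."""
    return SearchSpace(DEFAULT_SPACE.dimensions + (
        Dimension("log10_learning_rate", math.log10(1e-4), math.log10(3e-3),
                  "continuous"),
        Dimension("batch_index", 0, len(BATCH_CHOICES) - 1, "integer"),
    ))


def decode_position(coords: np.ndarray, space: SearchSpace) -> dict[str, float]:
    """Map internal continuous coordinates to named hyperparameter values.

    Integer dimensions are clipped to bounds then rounded half-up;
    continuous dimensions are clipped and passed through.
    """
    coords = space.clip(np.asarray(coords, dtype=float))
    out: dict[str, float] = {}
    for value, dim in zip(coords, space.dimensions):
        if dim.kind == "integer":
            out[dim.name] = int(min(dim.upper, max(dim.lower,
                                                   math.floor(value + 0.5))))
        else:
            out[dim.name] = float(value)
    return out


# ---------------------------------------------------------------------------
# Core algorithm
# ---------------------------------------------------------------------------

@dataclass
class WolfPosition:
    coordinates: np.ndarray
    fitness: float | None = None


def a_schedule(t: int, n_iters: int) -> float:
    """Linear exploration control: a(0) = 2, a(n_iters) = 0."""
    return 2.0 * (1.0 - t / n_iters)


def update_position(
    coords: np.ndarray,
    alpha: np.ndarray, beta: np.ndarray, delta: np.ndarray,
    a: float, rng: np.random.Generator, space: SearchSpace,
) -> np.ndarray:
    """One encircling update toward the three leaders, clipped to bounds."""
    if not (0.0 <= a <= 2.0):
        raise ValidationError(f"a must be in [0, 2], got {a}")
    coords = np.asarray(coords, dtype=float)
    parts = []
    for leader in (alpha, beta, delta):
        r1 = rng.random(coords.size)
        r2 = rng.random(coords.size)
        A = 2.0 * a * r1 - a
        C = 2.0 * r2
        D = np.abs(C * leader - coords)
        parts.append(leader - A * D)
    return space.clip((parts[0] + parts[1] + parts[2]) / 3.0)


@dataclass
class GWOState:
    """Pack state after one iteration (or initialization)."""
    population: list[WolfPosition]
    alpha: WolfPosition
    beta: WolfPosition
    delta: WolfPosition
    a: float
    iteration: int
    best_so_far: WolfPosition


def _rank(population: list[WolfPosition]) -> list[int]:
    """Indices sorted by fitness descending; ties keep lower index first."""
    return sorted(range(len(population)),
                  key=lambda i: (-population[i].fitness, i))


def gwo_optimize(
    fitness_fn,
    space: SearchSpace,
    n_wolves: int = 10,
    n_iters: int = 20,
    seed: int = 0,
    callback=None,
) -> tuple[WolfPosition, list[float]]:
    """Maximize ``fitness_fn`` over the search space.

    ``fitness_fn`` receives the decoded coordinate vector (integers already
    rounded) as a 1-D array.  A raising fitness function marks that wolf
    -inf and the search continues.  Repeated decoded positions are served
    from a cache, so at most ``n_wolves * (n_iters + 1)`` evaluations run.

    Returns the best position ever seen (tracked elitism: its fitness is
    non-decreasing over iterations) and the per-iteration best-so-far
    trajectory (length ``n_iters``).
    """
    if n_wolves < 3:
        raise ValidationError("the alpha/beta/delta hierarchy needs >= 3 wolves")
    if n_iters < 1:
        raise ValidationError("n_iters must be >= 1")
    rng = np.random.default_rng(seed)
    cache: dict[tuple, float] = {}

    def evaluate(coords: np.ndarray) -> float:
        decoded = decode_position(coords, space)
        key = tuple(decoded.values())
        if key in cache:
            return cache[key]
        try:
            fit = float(fitness_fn(np.array(list(decoded.values()), dtype=float)))
        except Exception:
            logger.exception("fitness evaluation failed; wolf set to -inf")
            fit = -math.inf
        cache[key] = fit
        return fit

    population = [WolfPosition(space.sample(rng)) for _ in range(n_wolves)]
    for w in population:
        w.fitness = evaluate(w.coordinates)

    order = _rank(population)
    best = WolfPosition(population[order[0]].coordinates.copy(),
                        population[order[0]].fitness)
    history: list[float] = []

    for t in range(1, n_iters + 1):
        a = a_schedule(t, n_iters)
        alpha, beta, delta = (population[order[k]].coordinates for k in range(3))
        for w in population:
            w.coordinates = update_position(
                w.coordinates, alpha, beta, delta, a, rng, space)
        for w in population:
            w.fitness = evaluate(w.coordinates)
        order = _rank(population)
        leader = population[order[0]]
        if leader.fitness > best.fitness:
            best = WolfPosition(leader.coordinates.copy(), leader.fitness)
        history.append(best.fitness)
        if callback is not None:
            callback(GWOState(
                population=population,
                alpha=population[order[0]], beta=population[order[1]],
                delta=population[order[2]], a=a, iteration=t, best_so_far=best,
            ))
    return best, history


# ---------------------------------------------------------------------------
# Hybrid-model fitness and tuner
# ---------------------------------------------------------------------------

def hparams_to_config(hparams: dict, input_len: int):
    """Build a HybridConfig (+ TrainConfig overrides) from decoded values.

    The searched filter count sets the first conv block; the second block
    gets half as many (floor, minimum 8).  Kernel size, stride and dropout
    apply to both blocks.
    """
    from .models import ConvBlock, HybridConfig

    n_filters = int(hparams["n_filters"])
    k = int(hparams["kernel_size"])
    s = int(hparams["stride"])
    drop = float(hparams["dropout"])
    blocks = (
        ConvBlock(filters=n_filters, kernel_size=k, stride=s, padding=1,
                  dropout_rate=drop, pool_size=2),
        ConvBlock(filters=max(8, n_filters // 2), kernel_size=k, stride=s,
                  padding=1, dropout_rate=drop, pool_size=2),
    )
    cfg = HybridConfig(blocks=blocks, lstm_hidden=int(hparams["lstm_units"]),
                       input_len=input_len)
    overrides = {}
    if "log10_learning_rate" in hparams:
        overrides["learning_rate"] = 10.0 ** hparams["log10_learning_rate"]
    if "batch_index" in hparams:
        overrides["batch_size"] = BATCH_CHOICES[int(hparams["batch_index"])]
    return cfg, overrides


def accuracy_fitness(
    hparams: dict,
    train: BeatDataset,
    valid: BeatDataset,
    budget,
) -> float:
    """Validation accuracy of a hybrid model trained under ``budget``.

    Infeasible architectures (e.g. strides that exhaust the input) score 0
    rather than aborting the search.
    """
    from .models import HybridCNNLSTM

    try:
        cfg, overrides = hparams_to_config(hparams, train.segment_len)
        model = HybridCNNLSTM(train, valid, cfg)
        results = model.fit(replace(budget, **overrides) if overrides else budget)
    except ConfigurationError as exc:
        logger.info("infeasible configuration scored 0: %s", exc)
        return 0.0
    return float(results.final_val_accuracy)


class GreyWolfTuner:
    """Hyperparameter search for the hybrid classifier, model-object style.

    ``fit()`` runs the pack search with validation accuracy as fitness and
    returns a :class:`TuningResults`.  Per-candidate training uses a
    reduced epoch budget (``fitness_epochs``, default 5); the winning
    configuration is meant to be retrained at full budget via
    :meth:`TuningResults.retrain`.
    """

    def __init__(
        self,
        train: BeatDataset,
        valid: BeatDataset,
        space: SearchSpace = DEFAULT_SPACE,
        n_wolves: int = 10,
        n_iters: int = 20,
        fitness_epochs: int = 5,
        seed: int = 0,
        train_config=None,
    ):
        from .models import TrainConfig

        self.train_data = train
        self.valid_data = valid
        self.space = space
        self.n_wolves = n_wolves
        self.n_iters = n_iters
        self.seed = seed
        base = train_config or TrainConfig(
            epochs=fitness_epochs, batch_size=20, learning_rate=1e-3,
            optimizer_name="adamw", seed=seed)
        self.budget = replace(base, epochs=fitness_epochs)
        self.eval_log: list[dict] = []

    def _fitness(self, decoded_vector: np.ndarray) -> float:
        # decoded_vector arrives pre-rounded; re-decoding restores exact ints
        hparams = decode_position(decoded_vector, self.space)
        fit = accuracy_fitness(hparams, self.train_data, self.valid_data,
                               self.budget)
        self.eval_log.append({"hparams": hparams, "fitness": fit})
        logger.info("evaluated %s -> %.4f", hparams, fit)
        return fit

    def fit(self) -> "TuningResults":
        best, history = gwo_optimize(
            self._fitness, self.space, self.n_wolves, self.n_iters, self.seed)
        best_hparams = decode_position(best.coordinates, self.space)
        return TuningResults(self, best, best_hparams, history,
                             list(self.eval_log))


@dataclass
class TuningResults:
    """Outcome of a pack search: the winning hyperparameters and the trail."""

    tuner: GreyWolfTuner
    best: WolfPosition
    best_hparams: dict
    history: list[float] = field(default_factory=list)
    eval_log: list[dict] = field(default_factory=list)

    @property
    def best_fitness(self) -> float:
        return self.best.fitness

    def retrain(self, epochs: int = 30, seed: int | None = None):
        """Train the best configuration at full budget; returns TrainingResults."""
        from .models import HybridCNNLSTM

        cfg, overrides = hparams_to_config(
            self.best_hparams, self.tuner.train_data.segment_len)
        budget = replace(self.tuner.budget, epochs=epochs, **overrides)
        if seed is not None:
            budget = replace(budget, seed=seed)
        model = HybridCNNLSTM(self.tuner.train_data, self.tuner.valid_data, cfg)
        return model.fit(budget)

    def summary(self) -> str:
        lines = [
            "Grey Wolf hyperparameter search",
            "=" * 44,
            f"wolves           {self.tuner.n_wolves:>10d}",
            f"iterations       {self.tuner.n_iters:>10d}",
            f"evaluations      {len(self.eval_log):>10d}",
            f"best fitness     {self.best_fitness:>10.4f}",
            "-" * 44,
        ]
        for name, value in self.best_hparams.items():
            if isinstance(value, float):
                lines.append(f"{name:<16s} {value:>10.4g}")
            else:
                lines.append(f"{name:<16s} {value:>10d}")
        return "\n".join(lines)
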