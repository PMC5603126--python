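"""Stage 3: genetic-algorithm wrapper selection with random-forest fitness.

Chromosomes are binary inclusion vectors over the candidate probes. Fitness
is the stratified cross-validated AUROC of a random forest trained on the
selected probes' beta values: out-of-fold predicted probabilities are pooled
and a single AUROC is computed, with the fold assignment and forest seed
fixed per GA run so fitness is a deterministic function of the chromosome
(and can be cached).

Each generation the top ``elitism_count`` individuals are copied unchanged
(strict elitism, so the best fitness never decreases), and the remainder of
the population is produced by size-2 tournament selection, two-point
crossover and per-bit mutation. The final panel is not the single best
chromosome: the best solutions (the elite set) of every generation after a
burn-in are collected and probes are ranked by how often they appear in
them (consensus counting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .evaluation import auroc
from .io import ConfigurationError, FeaturePanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    """Search and fitness parameters of the wrapper stage.

    The evolutionary parameters default to the study settings (population
    100, 100 generations, tournament size 2, 10 elites, two-point crossover
    with probability 0.6, per-bit mutation probability 0.05, initial
    chromosomes holding a random 30% of the candidates). ``burn_in_generation``
    and ``panel_size`` differ per comparison: 12/20 for normal-vs-cancer,
    20/12 for the LN contrast. The random-forest fitness uses
    ``fitness_cv_folds``-fold stratified CV with ``rf_n_trees`` trees; the
    small defaults keep a full wrapper run tractable on one core while leaving
    the AUROC ranking of subsets intact.
    """

    population_size: int = 100
    max_generations: int = 100
    tournament_size: int = 2
    elitism_count: int = 10
    crossover_prob: float = 0.6
    mutation_prob: float = 0.05
    init_fraction: float = 0.30
    burn_in_generation: int = 12
    panel_size: int = 20
    fitness_cv_folds: int = 2
    rf_n_trees: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.elitism_count >= self.population_size:
            raise ConfigurationError("elitism_count must be < population_size")
        if self.elitism_count < 0 or self.population_size < 1:
            raise ConfigurationError("population sizes must be positive")
        for name in ("crossover_prob", "mutation_prob", "init_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0 <= self.burn_in_generation < self.max_generations:
            raise ConfigurationError(
                "burn_in_generation must lie in [0, max_generations)"
            )
        if self.panel_size < 1:
            raise ConfigurationError("panel_size must be >= 1")
        if self.tournament_size < 1 or self.fitness_cv_folds < 2:
            raise ConfigurationError("tournament_size >= 1 and cv folds >= 2 required")


@dataclass
class GATrace:
    """Per-generation record of one GA run (generations are 1-based).

    ``best_chromosomes`` holds a copy of each generation's single best
    individual; ``elite_chromosomes`` the full elite set (the generation's
    ``elitism_count`` best individuals, fitness-sorted), which is what the
    consensus ranking counts over: with a deterministic fitness the single
    best individual turns over rarely once the search plateaus, whereas the
    elite set keeps churning at its lower ranks and so resolves which probes
    are common to all top solutions rather than private to one lineage.
    """

    candidates: tuple[str, ...]
    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_chromosomes: list[np.ndarray] = field(default_factory=list)
    elite_chromosomes: list[np.ndarray] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_generations(self) -> int:
        return len(self.best_fitness)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(1, self.n_generations + 1),
                "best_fitness": self.best_fitness,
                "mean_fitness": self.mean_fitness,
            }
        ).set_index("generation")


def initialize_population(
    n_candidates: int, cfg: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Random initial population: each chromosome holds exactly
    ``round(init_fraction * n_candidates)`` candidates (at least one)."""
    if n_candidates < 1:
        raise ConfigurationError("need at least one candidate probe")
    n_set = max(1, round(cfg.init_fraction * n_candidates))
    pop = np.zeros((cfg.population_size, n_candidates), dtype=bool)
    for i in range(cfg.population_size):
        pop[i, rng.choice(n_candidates, size=n_set, replace=False)] = True
    return pop


def tournament_select(
    fitness: np.ndarray, cfg: GAConfig, rng: np.random.Generator
) -> int:
    """Index of the winner of one tournament (draws with replacement; the
    first-drawn individual wins ties)."""
    contenders = rng.integers(0, fitness.size, size=cfg.tournament_size)
    best = contenders[0]
    for c in contenders[1:]:
        if fitness[c] > fitness[best]:
            best = c
    return int(best)


def two_point_crossover(
    a: np.ndarray, b: np.ndarray, cfg: GAConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Swap an internal segment [i, j) between two chromosomes with
    probability ``crossover_prob``; cut points satisfy 1 <= i < j <= L-1 so a
    proper segment is always exchanged."""
    child_a, child_b = a.copy(), b.copy()
    length = a.size
    if length >= 3 and rng.random() < cfg.crossover_prob:
        i, j = np.sort(rng.choice(np.arange(1, length), size=2, replace=False))
        child_a[i:j], child_b[i:j] = b[i:j].copy(), a[i:j].copy()
    return child_a, child_b


def mutate(chrom: np.ndarray, cfg: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``mutation_prob``; an
    all-zero result is repaired by setting one uniformly chosen bit."""
    flips = rng.random(chrom.size) < cfg.mutation_prob
    out = chrom ^ flips
    if not out.any():
        out[rng.integers(0, out.size)] = True
    return out


class FitnessEvaluator:
    """Deterministic chromosome fitness: pooled out-of-fold RF AUROC.

    Fold assignment and the forest's random state are fixed at construction,
    so the same chromosome always maps to the same fitness within a run;
    results are cached by bit pattern.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, cfg: GAConfig, rf_seed: int):
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("fitness evaluation requires exactly two classes")
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.cfg = cfg
        self.rf_seed = rf_seed
        splitter = StratifiedKFold(
            n_splits=cfg.fitness_cv_folds, shuffle=True, random_state=rf_seed
        )
        self.folds = list(splitter.split(self.X, self.y))
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def __call__(self, chrom: np.ndarray) -> float:
        key = np.packbits(chrom).tobytes()
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        if not chrom.any():
            raise ValueError("cannot evaluate an empty chromosome")
        X_sel = self.X[:, chrom]
        scores = np.empty(self.y.size)
        for train, test in self.folds:
            rf = RandomForestClassifier(
                n_estimators=self.cfg.rf_n_trees,
                random_state=self.rf_seed,
                n_jobs=1,
            )
            rf.fit(X_sel[train], self.y[train])
            pos = list(rf.classes_).index(rf.classes_.max())
            scores[test] = rf.predict_proba(X_sel[test])[:, pos]
        fitness = auroc(scores, self.y == self.y.max())
        self._cache[key] = fitness
        self.n_evaluations += 1
        return fitness


def run_ga(
    matrix: pd.DataFrame,
    labels,
    candidates,
    cfg: GAConfig,
) -> GATrace:
    """Run the full generational loop over the candidate probes.

    ``matrix`` is the probes x samples beta matrix (must contain all
    candidates); ``labels`` a binary vector over its columns. Returns the
    per-generation trace, including a copy of each generation's best
    chromosome for consensus counting. Fully reproducible from ``cfg.seed``.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ConfigurationError("GA needs at least 2 candidate probes")
    missing = [p for p in candidates if p not in matrix.index]
    if missing:
        raise ConfigurationError(f"candidates absent from matrix: {missing[:5]}")
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    rf_seed = int(ss.generate_state(1)[0] % (2**31 - 1))

    X = matrix.loc[candidates].to_numpy(dtype=float).T  # samples x candidates
    evaluate = FitnessEvaluator(X, np.asarray(labels), cfg, rf_seed)

    pop = initialize_population(len(candidates), cfg, rng)
    trace = GATrace(candidates=tuple(candidates), seed=cfg.seed)

    for _ in range(cfg.max_generations):
        fitness = np.array([evaluate(chrom) for chrom in pop])
        best_idx = int(np.argmax(fitness))  # first index on ties
        trace.best_fitness.append(float(fitness[best_idx]))
        trace.mean_fitness.append(float(fitness.mean()))
        trace.best_chromosomes.append(pop[best_idx].copy())

        # strict elitism: top individuals survive unchanged (stable sort so
        # ties keep population order)
        rank = np.argsort(-fitness, kind="stable")
        elite_idx = rank[: cfg.elitism_count]
        # collect the generation's best *distinct* solutions: elitism copies
        # mean the raw elite rows can be duplicates of one lineage, which
        # would double-count its probes in the consensus
        seen: set[bytes] = set()
        distinct: list[np.ndarray] = []
        for i in rank:
            key = np.packbits(pop[i]).tobytes()
            if key not in seen:
                seen.add(key)
                distinct.append(pop[i].copy())
            if len(distinct) == cfg.elitism_count:
                break
        trace.elite_chromosomes.append(np.array(distinct))
        next_pop = [pop[i].copy() for i in elite_idx]
        while len(next_pop) < cfg.population_size:
            p1 = pop[tournament_select(fitness, cfg, rng)]
            p2 = pop[tournament_select(fitness, cfg, rng)]
            c1, c2 = two_point_crossover(p1, p2, cfg, rng)
            next_pop.append(mutate(c1, cfg, rng))
            if len(next_pop) < cfg.population_size:
                next_pop.append(mutate(c2, cfg, rng))
        pop = np.array(next_pop)

    logger.info(
        "GA finished: %d generations, %d distinct chromosomes evaluated, "
        "final best fitness %.4f",
        trace.n_generations, evaluate.n_evaluations, trace.best_fitness[-1],
    )
    return trace


def consensus_counts(trace: GATrace, cfg: GAConfig) -> pd.Series:
    """How often each candidate appears in the collected best solutions.

    The best solutions of every generation after ``burn_in_generation`` — the
    elite set, i.e. each generation's ``elitism_count`` fittest individuals —
    are pooled and each probe's appearances are counted, so counts range from
    0 to (window length x elite-set size).
    """
    if trace.n_generations <= cfg.burn_in_generation:
        raise ConfigurationError(
            f"trace has {trace.n_generations} generations, needs more than "
            f"burn_in_generation={cfg.burn_in_generation}"
        )
    window = np.concatenate(trace.elite_chromosomes[cfg.burn_in_generation:])
    counts = window.sum(axis=0)
    return pd.Series(counts, index=list(trace.candidates), name="count")


def consensus_panel(
    trace: GATrace, cfg: GAConfig, comparison: str = ""
) -> FeaturePanel:
    """Top ``panel_size`` probes by consensus count (ties by probe ID)."""
    counts = consensus_counts(trace, cfg)
    ranked = sorted(counts.index, key=lambda p: (-counts[p], p))
    chosen = tuple(ranked[: cfg.panel_size])
    if len(chosen) < cfg.panel_size:
        logger.warning(
            "panel truncated to %d probes (only %d candidates)",
            len(chosen), len(ranked),
        )
    return FeaturePanel(
        comparison=comparison,
        probes=chosen,
        counts={p: int(counts[p]) for p in chosen},
    )
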