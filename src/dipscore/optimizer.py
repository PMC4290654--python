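"""Genetic-algorithm optimization of the scoring card.

The fitness of a candidate card is ``w1 * AUC + w2 * R`` where AUC is the
mean held-out ROC AUC over stratified cross-validation folds and R is the
Pearson correlation between the candidate's derived amino-acid
propensities and those of the frozen initial card.  The crossover
operator samples gene-group recombinations with a two-level orthogonal
array and composes a second child from the per-factor main effects.

Fold assignment is fixed once per optimization run, making fitness a
deterministic function of the chromosome; combined with elitism this
guarantees a non-decreasing best fitness across generations, and a fixed
seed makes the returned card bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from dipscore.metrics import confusion_metrics, pearson_r, roc_auc
from dipscore.scorecard import (
    SCORE_MAX,
    SCORE_MIN,
    ScoringCard,
    as_label_array,
    build_initial_card,
    propensity_vector,
    select_threshold,
)
from dipscore.seqio import ProteinRecord, dipeptide_count_matrix, pooled_composition

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitnessWeights:
    """Weights of the AUC and propensity-correlation terms of the fitness."""

    w1: float = 0.9
    w2: float = 0.1

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("fitness weights must be non-negative")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation layout used inside the fitness function."""

    folds: int = 10
    stratified: bool = True
    seed: int = 0
    pooled_auc: bool = False  # score all held-out folds jointly instead of averaging

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass(frozen=True)
class IGAConfig:
    """Genetic-algorithm settings.

    The 400 genes are partitioned into ``crossover_groups`` contiguous
    factor groups for the orthogonal-array crossover.  Scores are clamped
    to [0, 1000] after every variation step.
    """

    population_size: int = 20
    generations: int = 50
    crossover_groups: int = 15
    mutation_rate: float = 0.02
    mutation_step: float = 100.0
    init_noise: float = 50.0
    elitism: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.crossover_groups < 2:
            raise ValueError("crossover_groups must be >= 2")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.elitism < 1 or self.elitism >= self.population_size:
            raise ValueError("elitism must lie in [1, population_size)")


def assign_folds(labels: np.ndarray, cv: CVConfig) -> np.ndarray:
    """Deterministic fold index per sample (stratified when configured)."""
    rng = np.random.default_rng(cv.seed)
    n = len(labels)
    fold_of = np.empty(n, dtype=int)
    if cv.stratified:
        for cls in (True, False):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            fold_of[idx] = np.arange(len(idx)) % cv.folds
    else:
        idx = rng.permutation(n)
        fold_of[idx] = np.arange(n) % cv.folds
    return fold_of


class FitnessEvaluator:
    """Memoized fitness function over chromosomes (400-score arrays).

    Precomputes the per-record DPC matrix and the fold assignment so
    every evaluation is two matrix-vector products plus fold-wise AUCs.
    """

    def __init__(
        self,
        records: Sequence[ProteinRecord],
        labels: Sequence,
        weights: FitnessWeights,
        cv: CVConfig,
        init_propensities: np.ndarray,
    ):
        self.labels = as_label_array(labels)
        if self.labels.all() or not self.labels.any():
            raise ValueError("fitness requires both classes present")
        self.counts, self.totals = dipeptide_count_matrix(records)
        self.weights = weights
        self.cv = cv
        self.init_propensities = np.asarray(init_propensities, dtype=float)
        if np.ptp(self.init_propensities) == 0:
            raise ValueError("initial propensities have zero variance")
        self.fold_of = assign_folds(self.labels, cv)
        for f in range(cv.folds):
            fold_labels = self.labels[self.fold_of == f]
            if fold_labels.all() or not fold_labels.any():
                raise ValueError(f"fold {f} contains a single class")
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def sequence_scores(self, scores: np.ndarray) -> np.ndarray:
        return (self.counts @ scores) / self.totals

    def cv_auc(self, scores: np.ndarray) -> float:
        s = self.sequence_scores(scores)
        if self.cv.pooled_auc:
            return roc_auc(s, self.labels)
        aucs = [
            roc_auc(s[self.fold_of == f], self.labels[self.fold_of == f])
            for f in range(self.cv.folds)
        ]
        return float(np.mean(aucs))

    def __call__(self, scores: np.ndarray) -> float:
        key = scores.tobytes()
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        self.n_evaluations += 1
        auc = self.cv_auc(scores)
        prop = propensity_vector(scores)
        if np.ptp(prop) == 0:
            r = 0.0  # constant card carries no propensity signal
        else:
            r = pearson_r(prop, self.init_propensities)
        fit = self.weights.w1 * auc + self.weights.w2 * r
        self._cache[key] = fit
        return fit


def cross_validated_fitness(
    card: ScoringCard,
    records: Sequence[ProteinRecord],
    labels: Sequence,
    weights: FitnessWeights = FitnessWeights(),
    cv: CVConfig = CVConfig(),
    init_propensities: np.ndarray | None = None,
) -> float:
    """Fitness of one card: ``w1 * mean-CV-AUC + w2 * R(init, card propensities)``.

    When ``init_propensities`` is omitted the card's own propensities are
    used, making the R term exactly 1.
    """
    if init_propensities is None:
        init_propensities = propensity_vector(card.scores)
    evaluator = FitnessEvaluator(records, labels, weights, cv, init_propensities)
    return evaluator(card.scores)


def orthogonal_array(k: int) -> np.ndarray:
    """Two-level orthogonal array with n = 2^ceil(log2(k+1)) rows, k columns.

    Entry (i, j) is the parity of ``i AND mask_j`` where the masks are the
    first k non-zero row indices; every column is balanced and every
    column pair shows each level combination equally often.  Row 0 is all
    zeros (level 0 in every factor).
    """
    if k < 1:
        raise ValueError("need at least one factor")
    m = math.ceil(math.log2(k + 1))
    n = 2**m
    if k >= n:
        raise ValueError(f"array with {n} rows cannot host {k} factors")
    rows = np.arange(n)[:, None]
    masks = np.arange(1, k + 1)[None, :]
    return np.array(
        [[bin(int(r & c)).count("1") % 2 for c in masks[0]] for r in rows[:, 0]],
        dtype=int,
    )


def _factor_slices(n_genes: int, k: int) -> list[np.ndarray]:
    return np.array_split(np.arange(n_genes), k)


def oa_crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    k: int,
    evaluate: Callable[[np.ndarray], float],
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal-array crossover of two chromosomes.

    The genes are partitioned into ``k`` contiguous near-equal groups.
    Each orthogonal-array row selects, per group, genes from ``parent_a``
    (level 0) or ``parent_b`` (level 1); all rows plus ``parent_b`` itself
    are evaluated.  Returns ``(child_best, child_main_effects)``:
    the best evaluated candidate, and the chromosome composed from the
    per-factor level with the better main-effect mean fitness.
    """
    parent_a = np.asarray(parent_a, dtype=float)
    parent_b = np.asarray(parent_b, dtype=float)
    if parent_a.shape != parent_b.shape:
        raise ValueError("parents differ in shape")
    oa = orthogonal_array(k)
    groups = _factor_slices(parent_a.size, k)

    def compose(levels: np.ndarray) -> np.ndarray:
        child = parent_a.copy()
        for level, genes in zip(levels, groups):
            if level == 1:
                child[genes] = parent_b[genes]
        return np.clip(child, SCORE_MIN, SCORE_MAX)

    candidates = [compose(row) for row in oa]
    candidates.append(np.clip(parent_b, SCORE_MIN, SCORE_MAX))
    fitnesses = np.array([evaluate(c) for c in candidates])

    best_idx = int(np.argmax(fitnesses))  # first index on ties
    child_best = candidates[best_idx]

    row_fit = fitnesses[:-1]
    main_levels = np.empty(k, dtype=int)
    for j in range(k):
        mean0 = row_fit[oa[:, j] == 0].mean()
        mean1 = row_fit[oa[:, j] == 1].mean()
        main_levels[j] = 0 if mean0 >= mean1 else 1
    child_main = compose(main_levels)
    return child_best, child_main


def _tournament(rng: np.random.Generator, fitnesses: np.ndarray) -> int:
    i, j = rng.integers(0, len(fitnesses), size=2)
    return int(i) if fitnesses[i] >= fitnesses[j] else int(j)


def _mutate(rng: np.random.Generator, scores: np.ndarray, iga: IGAConfig) -> np.ndarray:
    mask = rng.random(scores.size) < iga.mutation_rate
    if mask.any():
        scores = scores.copy()
        scores[mask] += rng.uniform(-iga.mutation_step, iga.mutation_step, mask.sum())
        scores = np.clip(scores, SCORE_MIN, SCORE_MAX)
    return scores


def run_iga(
    records: Sequence[ProteinRecord],
    labels: Sequence,
    iga: IGAConfig = IGAConfig(),
    weights: FitnessWeights = FitnessWeights(),
    cv: CVConfig = CVConfig(),
) -> ScoringCard:
    """Optimize a scoring card against labeled records.

    The population starts from the initial difference-based card plus
    noisy copies.  Each generation keeps the ``elitism`` fittest
    individuals unchanged and fills the rest with mutated
    orthogonal-array crossover children of tournament-selected parents.
    Returns the best-ever card with a threshold selected on the full
    training data; metadata records the seed, fitness, cross-validated
    AUC, and the per-generation best/mean fitness history.
    """
    y = as_label_array(labels)
    if y.all() or not y.any():
        raise ValueError("training data must contain both classes")
    pos = [r for r, lab in zip(records, y) if lab]
    neg = [r for r, lab in zip(records, y) if not lab]
    init_card = build_initial_card(
        pooled_composition(pos, "DPC"), pooled_composition(neg, "DPC")
    )
    init_prop = propensity_vector(init_card.scores)
    evaluator = FitnessEvaluator(records, y, weights, cv, init_prop)

    rng = np.random.default_rng(iga.seed)
    population = [init_card.scores.copy()]
    for _ in range(iga.population_size - 1):
        noisy = init_card.scores + rng.uniform(-iga.init_noise, iga.init_noise, 400)
        population.append(np.clip(noisy, SCORE_MIN, SCORE_MAX))

    best_scores = population[0]
    best_fit = -np.inf
    history: list[tuple[int, float, float]] = []
    for gen in range(iga.generations):
        fitnesses = np.array([evaluator(ind) for ind in population])
        gen_best = int(np.argmax(fitnesses))
        if fitnesses[gen_best] > best_fit:
            best_fit = float(fitnesses[gen_best])
            best_scores = population[gen_best].copy()
        history.append((gen, float(fitnesses.max()), float(fitnesses.mean())))
        logger.debug(
            "generation %d: best=%.6f mean=%.6f", gen, fitnesses.max(), fitnesses.mean()
        )
        order = np.argsort(-fitnesses, kind="stable")
        next_pop = [population[i].copy() for i in order[: iga.elitism]]
        while len(next_pop) < iga.population_size:
            pa = population[_tournament(rng, fitnesses)]
            pb = population[_tournament(rng, fitnesses)]
            for child in oa_crossover(pa, pb, iga.crossover_groups, evaluator):
                if len(next_pop) < iga.population_size:
                    next_pop.append(_mutate(rng, child, iga))
        population = next_pop

    # Final population may contain an improvement from the last variation.
    fitnesses = np.array([evaluator(ind) for ind in population])
    gen_best = int(np.argmax(fitnesses))
    if fitnesses[gen_best] > best_fit:
        best_fit = float(fitnesses[gen_best])
        best_scores = population[gen_best].copy()

    train_scores = evaluator.sequence_scores(best_scores)
    threshold = select_threshold(train_scores, y)
    return ScoringCard(
        scores=best_scores,
        threshold=threshold,
        provenance="optimized",
        metadata={
            "seed": iga.seed,
            "fitness": best_fit,
            "cv_auc": evaluator.cv_auc(best_scores),
            "init_fitness": evaluator(init_card.scores),
            "n_evaluations": evaluator.n_evaluations,
            "history": history,
        },
    )


@dataclass(frozen=True)
class SubsetReport:
    """Training metrics of the card fitted to one resampled negative subset."""

    subset: int
    accuracy: float
    mcc: float
    sensitivity: float
    specificity: float
    cv_auc: float


def train_with_negative_resampling(
    pos: Sequence[ProteinRecord],
    neg_pool: Sequence[ProteinRecord],
    n_subsets: int,
    subset_size: int,
    seed: int,
    iga: IGAConfig = IGAConfig(),
    weights: FitnessWeights = FitnessWeights(),
    cv: CVConfig = CVConfig(),
) -> tuple[ScoringCard, list[SubsetReport]]:
    """Train one card per random negative subset; keep the most accurate.

    Each of the ``n_subsets`` subsets of ``subset_size`` negatives is
    drawn without replacement from the pool with an independently derived
    seed, paired with all positives, and used to train a card.  Reported
    accuracy is resubstitution accuracy at the selected threshold.
    Returns the best card (ties keep the earlier subset) and the
    per-subset reports.
    """
    if len(neg_pool) < subset_size:
        raise ValueError(
            f"negative pool has {len(neg_pool)} records, need {subset_size}"
        )
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    subset_seeds = np.random.SeedSequence(seed).spawn(n_subsets)
    reports: list[SubsetReport] = []
    best_card: ScoringCard | None = None
    best_acc = -np.inf
    for i, subset_seed in enumerate(subset_seeds):
        draw_seed, iga_seed = subset_seed.spawn(2)
        rng = np.random.default_rng(draw_seed)
        chosen = rng.choice(len(neg_pool), size=subset_size, replace=False)
        negatives = [neg_pool[j] for j in sorted(chosen)]
        records = list(pos) + negatives
        labels = [True] * len(pos) + [False] * len(negatives)
        sub_iga = IGAConfig(
            population_size=iga.population_size,
            generations=iga.generations,
            crossover_groups=iga.crossover_groups,
            mutation_rate=iga.mutation_rate,
            mutation_step=iga.mutation_step,
            init_noise=iga.init_noise,
            elitism=iga.elitism,
            seed=int(np.random.default_rng(iga_seed).integers(2**31)),
        )
        card = run_iga(records, labels, sub_iga, weights, cv)
        C, totals = dipeptide_count_matrix(records)
        summary = confusion_metrics((C @ card.scores) / totals, labels, card.threshold)
        reports.append(
            SubsetReport(
                subset=i + 1,
                accuracy=summary.accuracy,
                mcc=summary.mcc,
                sensitivity=summary.sensitivity,
                specificity=summary.specificity,
                cv_auc=card.metadata["cv_auc"],
            )
        )
        if summary.accuracy > best_acc:
            best_acc = summary.accuracy
            best_card = card
    return best_card, reports
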