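import numpy as np
import pytest

from dipscore.metrics import roc_auc
from dipscore.optimizer import (
    CVConfig,
    FitnessEvaluator,
    FitnessWeights,
    IGAConfig,
    assign_folds,
    cross_validated_fitness,
    oa_crossover,
    orthogonal_array,
    run_iga,
    train_with_negative_resampling,
)
from dipscore.scorecard import ScoringCard, build_initial_card, propensity_vector
from dipscore.seqio import ProteinRecord, dpc_matrix, pooled_composition
from dipscore.synthetic import SyntheticSpec, generate_dataset

SMALL_IGA = IGAConfig(population_size=6, generations=4, crossover_groups=7, seed=5)
SMALL_CV = CVConfig(folds=3, seed=5)


@pytest.fixture(scope="module")
def enriched_data():
    spec = SyntheticSpec(
        n_pos=30, n_neg=30, length_min=60, length_max=90, beta=0.08, seed=7
    )
    return generate_dataset(spec)


class TestConfigs:
    def test_default_weights(self):
        w = FitnessWeights()
        assert (w.w1, w.w2) == (0.9, 0.1)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            FitnessWeights(w1=-0.1)

    def test_cv_folds_minimum(self):
        with pytest.raises(ValueError):
            CVConfig(folds=1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"population_size": 3},
            {"crossover_groups": 1},
            {"mutation_rate": 1.5},
            {"elitism": 0},
            {"elitism": 20, "population_size": 20},
        ],
    )
    def test_iga_validation(self, kwargs):
        with pytest.raises(ValueError):
            IGAConfig(**kwargs)


class TestAssignFolds:
    def test_partition(self):
        labels = np.array([True] * 20 + [False] * 20)
        fold_of = assign_folds(labels, CVConfig(folds=5, seed=3))
        assert fold_of.shape == (40,)
        for f in range(5):
            assert (fold_of == f).sum() == 8

    def test_stratification(self):
        labels = np.array([True] * 20 + [False] * 20)
        fold_of = assign_folds(labels, CVConfig(folds=5, seed=3))
        for f in range(5):
            fold_labels = labels[fold_of == f]
            assert fold_labels.sum() == 4

    def test_deterministic(self):
        labels = np.array([True] * 15 + [False] * 15)
        a = assign_folds(labels, CVConfig(folds=3, seed=9))
        b = assign_folds(labels, CVConfig(folds=3, seed=9))
        assert (a == b).all()


class TestCrossValidatedFitness:
    def test_perfect_card_and_correlation(self):
        # two pure-homopolymer classes and a card separating them gives
        # AUC 1 in every fold; R against the card's own propensities is 1
        records = [ProteinRecord(f"p{i}", "ADADADAD") for i in range(6)]
        records += [ProteinRecord(f"n{i}", "CECECECE") for i in range(6)]
        labels = [True] * 6 + [False] * 6
        scores = np.full(400, 0.0)
        from dipscore.seqio import DIPEPTIDE_INDEX

        for dp in ("AD", "DA"):
            scores[DIPEPTIDE_INDEX[dp]] = 1000.0
        card = ScoringCard(scores)
        fit = cross_validated_fitness(
            card, records, labels, FitnessWeights(), CVConfig(folds=3, seed=0)
        )
        assert fit == pytest.approx(0.9 + 0.1)

    def test_auc_only_weights(self, enriched_data):
        records, labels = enriched_data
        pos = [r for r, lab in zip(records, labels) if lab]
        neg = [r for r, lab in zip(records, labels) if not lab]
        card = build_initial_card(
            pooled_composition(pos, "DPC"), pooled_composition(neg, "DPC")
        )
        evaluator = FitnessEvaluator(
            records, labels, FitnessWeights(1.0, 0.0), SMALL_CV,
            propensity_vector(card.scores),
        )
        assert evaluator(card.scores) == pytest.approx(evaluator.cv_auc(card.scores))

    def test_initial_card_beats_uniform(self, enriched_data):
        records, labels = enriched_data
        pos = [r for r, lab in zip(records, labels) if lab]
        neg = [r for r, lab in zip(records, labels) if not lab]
        init = build_initial_card(
            pooled_composition(pos, "DPC"), pooled_composition(neg, "DPC")
        )
        evaluator = FitnessEvaluator(
            records, labels, FitnessWeights(), SMALL_CV, propensity_vector(init.scores)
        )
        # a uniform card scores every sequence identically: AUC 0.5
        assert evaluator.cv_auc(np.full(400, 500.0)) == pytest.approx(0.5)
        assert evaluator(init.scores) > 0.9 * 0.5 + 0.1

    def test_single_class_rejected(self):
        records = [ProteinRecord(f"p{i}", "ACDE") for i in range(4)]
        with pytest.raises(ValueError):
            FitnessEvaluator(
                records, [True] * 4, FitnessWeights(), SMALL_CV, np.arange(20.0)
            )


class TestOrthogonalArray:
    def test_l4_structure(self):
        oa = orthogonal_array(3)
        assert oa.shape == (4, 3)
        # row 0 all level-0; every column balanced
        assert (oa[0] == 0).all()
        for j in range(3):
            assert oa[:, j].sum() == 2

    def test_pairwise_balance(self):
        for k in (3, 7, 15):
            oa = orthogonal_array(k)
            n = oa.shape[0]
            for j in range(k):
                for l in range(j + 1, k):
                    combos = list(zip(oa[:, j], oa[:, l]))
                    for pair in ((0, 0), (0, 1), (1, 0), (1, 1)):
                        assert combos.count(pair) == n // 4

    def test_row_count(self):
        assert orthogonal_array(3).shape[0] == 4
        assert orthogonal_array(4).shape[0] == 8
        assert orthogonal_array(15).shape[0] == 16

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            orthogonal_array(0)


class TestOaCrossover:
    def test_identical_parents(self):
        parent = np.linspace(0, 1000, 400)
        best, main = oa_crossover(parent, parent.copy(), 7, lambda s: float(s.sum()))
        assert (best == parent).all()
        assert (main == parent).all()

    def test_child_best_dominates_parents(self, rng):
        # fitness is an arbitrary deterministic function; both parents are
        # among the evaluated candidates so the best child cannot lose
        for _ in range(5):
            pa = rng.uniform(0, 1000, 400)
            pb = rng.uniform(0, 1000, 400)
            weights = rng.normal(size=400)

            def fit(s):
                return float(weights @ s)

            best, _ = oa_crossover(pa, pb, 7, fit)
            assert fit(best) >= fit(pa) - 1e-9
            assert fit(best) >= fit(pb) - 1e-9

    def test_children_in_range(self, rng):
        pa = rng.uniform(0, 1000, 400)
        pb = rng.uniform(0, 1000, 400)
        best, main = oa_crossover(pa, pb, 15, lambda s: float(s[0]))
        for child in (best, main):
            assert child.min() >= 0.0 and child.max() <= 1000.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            oa_crossover(np.zeros(400), np.zeros(399), 7, lambda s: 0.0)


@pytest.fixture(scope="module")
def trained(enriched_data):
    records, labels = enriched_data
    return run_iga(records, labels, SMALL_IGA, FitnessWeights(), SMALL_CV)


class TestRunIga:
    def test_best_fitness_nondecreasing(self, trained):
        best = [b for _, b, _ in trained.metadata["history"]]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(best, best[1:]))

    def test_scores_in_range(self, trained):
        assert trained.scores.min() >= 0.0
        assert trained.scores.max() <= 1000.0

    def test_beats_initial_card(self, trained):
        assert trained.metadata["fitness"] >= trained.metadata["init_fitness"] - 1e-12

    def test_threshold_set_and_provenance(self, trained):
        assert trained.threshold is not None
        assert trained.provenance == "optimized"

    def test_bit_reproducible(self, enriched_data):
        records, labels = enriched_data
        a = run_iga(records, labels, SMALL_IGA, FitnessWeights(), SMALL_CV)
        b = run_iga(records, labels, SMALL_IGA, FitnessWeights(), SMALL_CV)
        assert a.scores.tobytes() == b.scores.tobytes()
        assert a.threshold == b.threshold

    def test_single_class_fatal(self):
        records = [ProteinRecord(f"p{i}", "ACDE") for i in range(6)]
        with pytest.raises(ValueError):
            run_iga(records, [True] * 6, SMALL_IGA, FitnessWeights(), SMALL_CV)

    def test_no_skill_on_fresh_null_data(self):
        # with no class signal the trained card must not generalize:
        # AUC on an independently generated null dataset stays near 0.5
        spec = SyntheticSpec(
            n_pos=60, n_neg=60, length_min=80, length_max=80,
            beta=0.0, enriched_dipeptides=(), seed=31,
        )
        records, labels = generate_dataset(spec)
        card = run_iga(records, labels, SMALL_IGA, FitnessWeights(), SMALL_CV)
        fresh_records, fresh_labels = generate_dataset(
            SyntheticSpec(
                n_pos=100, n_neg=100, length_min=80, length_max=80,
                beta=0.0, enriched_dipeptides=(), seed=32,
            )
        )
        auc = roc_auc(dpc_matrix(fresh_records) @ card.scores, fresh_labels)
        assert 0.35 <= auc <= 0.65


class TestNegativeResampling:
    def test_single_subset_matches_manual_run(self, enriched_data):
        records, labels = enriched_data
        pos = [r for r, lab in zip(records, labels) if lab]
        neg = [r for r, lab in zip(records, labels) if not lab]
        card, reports = train_with_negative_resampling(
            pos, neg, n_subsets=1, subset_size=len(pos), seed=3,
            iga=SMALL_IGA, cv=SMALL_CV,
        )
        assert len(reports) == 1
        assert card.provenance == "optimized"
        assert 0.0 <= reports[0].accuracy <= 1.0

    def test_report_shape_and_best_choice(self, enriched_data):
        records, labels = enriched_data
        pos = [r for r, lab in zip(records, labels) if lab]
        neg = [r for r, lab in zip(records, labels) if not lab]
        tiny = IGAConfig(population_size=4, generations=2, crossover_groups=3, seed=5)
        card, reports = train_with_negative_resampling(
            pos, neg, n_subsets=3, subset_size=20, seed=11, iga=tiny, cv=SMALL_CV
        )
        assert [r.subset for r in reports] == [1, 2, 3]
        for rep in reports:
            assert 0.0 <= rep.accuracy <= 1.0
            assert -1.0 <= rep.mcc <= 1.0

    def test_pool_too_small(self, enriched_data):
        records, labels = enriched_data
        pos = [r for r, lab in zip(records, labels) if lab]
        with pytest.raises(ValueError):
            train_with_negative_resampling(
                pos, pos[:3], n_subsets=2, subset_size=10, seed=0
            )

    def test_deterministic(self, enriched_data):
        records, labels = enriched_data
        pos = [r for r, lab in zip(records, labels) if lab]
        neg = [r for r, lab in zip(records, labels) if not lab]
        tiny = IGAConfig(population_size=4, generations=2, crossover_groups=3, seed=5)
        card1, rep1 = train_with_negative_resampling(
            pos, neg, n_subsets=2, subset_size=15, seed=21, iga=tiny, cv=SMALL_CV
        )
        card2, rep2 = train_with_negative_resampling(
            pos, neg, n_subsets=2, subset_size=15, seed=21, iga=tiny, cv=SMALL_CV
        )
        assert card1.scores.tobytes() == card2.scores.tobytes()
        assert rep1 == rep2
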