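# dipscore

Dipeptide propensity score cards for two-class protein sequence
classification.

`dipscore` estimates, for each of the 400 ordered dipeptides, a propensity
score in [0, 1000] that quantifies how strongly the dipeptide favors the
positive class of a labeled training set. A sequence is scored by the
weighted sum of card scores, weighted by its dipeptide composition, and
classified positive when the score strictly exceeds a learned threshold.
The initial card (class composition difference, min–max normalized) can be
refined by a genetic algorithm whose crossover samples gene-group
recombinations with a two-level orthogonal array; the fitness is
`w1 * AUC + w2 * R`, where AUC is the mean held-out ROC AUC over stratified
10-fold cross-validation and R is the Pearson correlation between the
candidate's derived per-amino-acid propensities and those of the initial
card. Derived amino-acid propensities can then be correlated against
AAindex physicochemical property scales to nominate properties that
characterize the positive class (candidates at |R| > 0.5).

## Package layout

| module | contents |
|---|---|
| `dipscore.seqio` | FASTA reading/validation, amino-acid and dipeptide composition vectors |
| `dipscore.scorecard` | `ScoringCard`, initial-card construction, scoring, threshold selection, classification, ranking, card file I/O |
| `dipscore.metrics` | confusion metrics, rank-based ROC AUC, Pearson correlation, two-sample rank-sum test (exact for small groups) |
| `dipscore.optimizer` | cross-validated fitness, orthogonal-array crossover, the genetic-algorithm driver, negative-subset resampling |
| `dipscore.pcp` | AAindex1 parsing, propensity–property correlation ranking, per-sequence/group property summaries |
| `dipscore.synthetic` | seeded two-class generator with controlled dipeptide enrichment; packaged reference tables |
| `dipscore.cli` | the `dipscore` command-line tool |

## Command-line usage

```sh
# generate a synthetic labeled dataset
dipscore synth --out data.fasta --labels labels.tsv --n-pos 200 --n-neg 200 \
    --length-min 300 --length-max 300 --beta 0.05 --seed 1

# train a card (positive and negative FASTA files)
dipscore train --pos pos.fasta --neg neg.fasta --out-card card.tsv \
    --report report.tsv --seed 1

# or train against a large negative pool with subset resampling
dipscore train --pos pos.fasta --neg-pool pool.fasta --n-subsets 10 \
    --out-card card.tsv --report report.tsv --seed 1

# score and classify query sequences
dipscore predict --card card.tsv --query query.fasta --out predictions.tsv

# rank a sequence pool by descending score
dipscore rank --card card.tsv --pool pool.fasta --top 20

# correlate card propensities against AAindex property scales
dipscore pcp --card card.tsv --aaindex aaindex1.txt --cutoff 0.5
```

Optimizer, cross-validation, and fitness-weight settings can also be given
in a YAML config file (`--config`); explicit flags take precedence. All
reports are tab-separated with `#` metadata lines; identical inputs and
seeds reproduce byte-identical outputs. Exit codes: 0 success, 2 input
error, 3 configuration error.

## Tests and acceptance report

```sh
python -m pytest -q tests/            # ~2.5 minutes on one CPU
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion,
including a full-scale seeded parameter-recovery run (enriched dipeptides
must be recovered into the top 5% of card scores, held-out accuracy >= 0.9,
and a null dataset must yield a pipeline-level cross-validated AUC near
0.5). `scripts/acceptance.py` recomputes the reference-table correlation
and composition targets from the packaged data and writes them as JSON.

## Packaged data

`dipscore/data/` ships plain-text reference tables of per-amino-acid
propensity scores with class compositions, three physicochemical property
scales (SNEP660103, TAKK010101, KARP850101), and mean C-alpha B-factors,
plus a small AAindex1-format excerpt containing those three scales. They
are exposed through `dipscore.synthetic.propensity_composition_table()`
and friends.
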