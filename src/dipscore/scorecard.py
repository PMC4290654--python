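"""The 400-dipeptide propensity scoring card.

A card maps every ordered dipeptide to a propensity score in [0, 1000].
A sequence is scored by the weighted sum of card scores, weighted by its
dipeptide composition, and classified positive when the score strictly
exceeds the card's threshold.  Per-amino-acid propensities are derived by
averaging the 40 dipeptide scores whose dipeptides contain the residue
(the self-pair XX contributing twice).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from dipscore.seqio import (
    AMINO_ACIDS,
    DIPEPTIDE_INDEX,
    DIPEPTIDES,
    CompositionVector,
    ProteinRecord,
    dipeptide_counts,
)

SCORE_MIN = 0.0
SCORE_MAX = 1000.0

# (20, 400) operator: propensity = _PROPENSITY_OP @ scores.  Row X holds
# 1/40 for each dipeptide containing X, with 2/40 on the diagonal pair XX.
_PROPENSITY_OP = np.zeros((20, 400))
for _i, _aa in enumerate(AMINO_ACIDS):
    for _j, _dp in enumerate(DIPEPTIDES):
        _PROPENSITY_OP[_i, _j] = (_dp[0] == _aa) + (_dp[1] == _aa)
_PROPENSITY_OP /= 40.0

# Variant that averages over the 39 distinct dipeptides containing X.
_PROPENSITY_OP_DISTINCT = np.minimum(_PROPENSITY_OP * 40.0, 1.0) / 39.0


def derive_aa_propensities(
    scores: np.ndarray | "ScoringCard", double_count_self: bool = True
) -> dict[str, float]:
    """Per-amino-acid propensities from the 400 dipeptide scores.

    propensity(X) is the mean of the 40 scores of dipeptides X· and ·X;
    the pair XX appears in both groups and is counted twice.  Setting
    ``double_count_self=False`` averages the 39 distinct dipeptides
    instead.
    """
    if isinstance(scores, ScoringCard):
        scores = scores.scores
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (400,):
        raise ValueError(f"expected 400 scores, got shape {scores.shape}")
    op = _PROPENSITY_OP if double_count_self else _PROPENSITY_OP_DISTINCT
    values = op @ scores
    return {aa: float(v) for aa, v in zip(AMINO_ACIDS, values)}


def propensity_vector(scores: np.ndarray, double_count_self: bool = True) -> np.ndarray:
    """Vectorized form of :func:`derive_aa_propensities` (alphabetical order)."""
    op = _PROPENSITY_OP if double_count_self else _PROPENSITY_OP_DISTINCT
    return op @ np.asarray(scores, dtype=float)


@dataclass(frozen=True)
class ScoringCard:
    """400 dipeptide propensity scores plus a decision threshold.

    ``scores`` follows the alphabetical dipeptide order of
    :data:`dipscore.seqio.DIPEPTIDES` and every entry lies in [0, 1000].
    ``provenance`` tags the card ``"initial"`` or ``"optimized"``;
    ``metadata`` carries training details (seed, fitness, history).
    """

    scores: np.ndarray = field(repr=False)
    threshold: float | None = None
    provenance: str = "initial"
    metadata: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (400,):
            raise ValueError(f"card must have exactly 400 scores, got {scores.shape}")
        if np.any(scores < SCORE_MIN) or np.any(scores > SCORE_MAX):
            raise ValueError("card scores must lie in [0, 1000]")
        object.__setattr__(self, "scores", scores)

    @property
    def aa_propensities(self) -> dict[str, float]:
        return derive_aa_propensities(self.scores)

    def score(self, dipeptide: str) -> float:
        return float(self.scores[DIPEPTIDE_INDEX[dipeptide]])

    def with_threshold(self, threshold: float) -> "ScoringCard":
        return replace(self, threshold=float(threshold))


def build_initial_card(
    pos_dpc: CompositionVector, neg_dpc: CompositionVector
) -> ScoringCard:
    """Initial card from class dipeptide compositions.

    Raw score_i = pos_i - neg_i, then linearly min-max mapped onto
    [0, 1000].  If all raw differences are equal (no contrast) every score
    is set to 500.  The default threshold is the median of the 400 scores,
    a placeholder until a threshold is selected against training data.
    """
    for v in (pos_dpc, neg_dpc):
        if not isinstance(v, CompositionVector) or v.kind != "DPC":
            raise ValueError("build_initial_card requires DPC-400 composition vectors")
    raw = pos_dpc.values - neg_dpc.values
    lo, hi = raw.min(), raw.max()
    if hi - lo == 0:
        scores = np.full(400, 500.0)
    else:
        scores = (raw - lo) / (hi - lo) * 1000.0
    return ScoringCard(
        scores=scores,
        threshold=float(np.median(scores)),
        provenance="initial",
    )


def score_sequence(card: ScoringCard, record: ProteinRecord) -> float:
    """Weighted-sum score: sum over dipeptides of DPC weight times card score.

    Since the weights sum to 1 and scores lie in [0, 1000], the result is
    a convex combination of card scores, bounded by the card's min and max.
    """
    counts = dipeptide_counts(record.sequence)
    return float((counts @ card.scores) / counts.sum())


def score_records(card: ScoringCard, records: Sequence[ProteinRecord]) -> np.ndarray:
    return np.array([score_sequence(card, r) for r in records])


def as_label_array(labels: Sequence) -> np.ndarray:
    """Normalize labels ({pos,neg}, {1,0}, bools) to a boolean array."""
    out = []
    for lab in labels:
        if isinstance(lab, str):
            if lab not in ("pos", "neg"):
                raise ValueError(f"unrecognized label {lab!r}")
            out.append(lab == "pos")
        else:
            out.append(bool(lab))
    return np.array(out, dtype=bool)


def select_threshold(scores: Sequence[float], labels: Sequence) -> float:
    """Threshold maximizing training accuracy under the strict ``>`` rule.

    Candidate cuts are the midpoints between adjacent distinct sorted
    score values, plus one sentinel below the minimum (everything
    positive) and one above the maximum (everything negative).  Ties in
    accuracy are broken by minimizing |sensitivity - specificity|, then
    by the smaller threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = as_label_array(labels)
    if len(s) != len(y):
        raise ValueError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("select_threshold requires both classes present")
    uniq = np.unique(s)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best = None
    for t in candidates:
        pred = s > t
        tp = int(np.sum(pred & y))
        tn = int(np.sum(~pred & ~y))
        acc = (tp + tn) / len(y)
        sens = tp / n_pos
        spec = tn / n_neg
        key = (-acc, abs(sens - spec), t)
        if best is None or key < best[0]:
            best = (key, t)
    return float(best[1])


def classify(card: ScoringCard, record: ProteinRecord) -> str:
    """``"pos"`` iff the sequence score strictly exceeds the card threshold."""
    if card.threshold is None:
        raise ValueError("card has no threshold set")
    return "pos" if score_sequence(card, record) > card.threshold else "neg"


def rank_sequences(
    card: ScoringCard, records: Sequence[ProteinRecord], top_k: int
) -> list[tuple[str, float]]:
    """Top-k records by descending score; ties keep input order."""
    if not records:
        raise ValueError("no records to rank")
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    scores = score_records(card, records)
    order = np.argsort(-scores, kind="stable")
    return [(records[i].id, float(scores[i])) for i in order[:top_k]]


def write_card(card: ScoringCard, path: str | Path) -> None:
    """Write a card as tab-separated text (bit-exact round trip).

    Three sections: 400 ``dipeptide<TAB>score`` rows, 20
    ``aa<TAB>propensity`` rows, one ``threshold<TAB>value`` row.  Floats
    are written with ``repr`` so reading recovers identical doubles.
    """
    lines = [f"# dipscore card\tprovenance={card.provenance}"]
    for dp, s in zip(DIPEPTIDES, card.scores):
        lines.append(f"{dp}\t{float(s)!r}")
    for aa, p in card.aa_propensities.items():
        lines.append(f"{aa}\t{p!r}")
    thr = "NA" if card.threshold is None else repr(float(card.threshold))
    lines.append(f"threshold\t{thr}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_card(path: str | Path) -> ScoringCard:
    """Read a card written by :func:`write_card`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such card file: {path}")
    scores = np.full(400, np.nan)
    threshold: float | None = None
    provenance = "initial"
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            if "provenance=" in line:
                provenance = line.split("provenance=", 1)[1].strip()
            continue
        key, value = line.split("\t")
        if key == "threshold":
            threshold = None if value == "NA" else float(value)
        elif len(key) == 2 and key in DIPEPTIDE_INDEX:
            scores[DIPEPTIDE_INDEX[key]] = float(value)
        elif len(key) == 1 and key in AMINO_ACIDS:
            continue  # propensities are derived, not stored state
        else:
            raise ValueError(f"unrecognized card row key {key!r}")
    if np.isnan(scores).any():
        missing = int(np.isnan(scores).sum())
        raise ValueError(f"card file missing {missing} dipeptide score(s)")
    return ScoringCard(scores=scores, threshold=threshold, provenance=provenance)
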