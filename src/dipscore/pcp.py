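"""Correlating amino-acid propensities with physicochemical property scales.

Parses AAindex1-format flat files, ranks property scales by the absolute
Pearson correlation with a 20-value propensity (or composition) vector,
and provides per-sequence and group-level property summaries.  All
20-vector joins use the fixed alphabetical residue order; tables are
re-indexed on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from dipscore.metrics import mann_whitney, pearson_r
from dipscore.seqio import AA_INDEX, AMINO_ACIDS, CompositionVector, ProteinRecord

logger = logging.getLogger(__name__)

# Residue order of the two value lines in an AAindex1 record.
_AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class AAindexEntry:
    """One AAindex property scale: accession, description, 20 values.

    ``values`` is ordered alphabetically by one-letter code, with NaN for
    missing ("NA") slots; ``complete`` is False iff any slot is missing.
    """

    accession: str
    description: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (20,):
            raise ValueError(
                f"entry {self.accession}: expected 20 values, got shape {vals.shape}"
            )
        object.__setattr__(self, "values", vals)

    @property
    def complete(self) -> bool:
        return not np.isnan(self.values).any()

    def value(self, aa: str) -> float:
        return float(self.values[AA_INDEX[aa]])


@dataclass(frozen=True)
class CorrelationHit:
    """Correlation of one property scale with the propensity vector.

    ``candidate`` is True iff |r| exceeded the cutoff in force when the
    hit was produced.
    """

    accession: str
    r: float
    candidate: bool


def _make_hit(accession: str, r: float, cutoff: float) -> CorrelationHit:
    return CorrelationHit(accession=accession, r=r, candidate=abs(r) > cutoff)


def parse_aaindex(path: str | Path) -> list[AAindexEntry]:
    """Parse an AAindex1 flat file into property entries.

    Records are delimited by ``//``; the accession follows ``H``, the
    description follows ``D`` (continuation lines allowed), and the 20
    values sit on the two lines after the ``I`` header in
    A/R/N/D/C/Q/E/G/H/I then L/K/M/F/P/S/T/W/Y/V order.  ``NA`` tokens
    become NaN.  A record with the wrong value count raises ``ValueError``
    naming its accession.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such AAindex file: {path}")
    entries: list[AAindexEntry] = []
    accession = ""
    description_parts: list[str] = []
    value_tokens: list[str] = []
    in_values = in_description = False
    for line in path.read_text().splitlines():
        if line.startswith("//"):
            if accession:
                entries.append(_finish_entry(accession, description_parts, value_tokens))
            accession = ""
            description_parts = []
            value_tokens = []
            in_values = in_description = False
        elif line.startswith("H "):
            accession = line[2:].strip()
            in_values = in_description = False
        elif line.startswith("D "):
            description_parts.append(line[2:].strip())
            in_description = True
            in_values = False
        elif line.startswith("I "):
            in_values = True
            in_description = False
        elif line.startswith(" ") and in_values:
            value_tokens.extend(line.split())
        elif line.startswith(" ") and in_description:
            description_parts.append(line.strip())
        else:
            in_values = in_description = False
    if accession:  # file without trailing terminator
        entries.append(_finish_entry(accession, description_parts, value_tokens))
    return entries


def _finish_entry(
    accession: str, description_parts: list[str], tokens: list[str]
) -> AAindexEntry:
    if len(tokens) != 20:
        raise ValueError(
            f"entry {accession}: expected 20 values, found {len(tokens)}"
        )
    by_aa = {}
    for aa, tok in zip(_AAINDEX_ORDER, tokens):
        by_aa[aa] = np.nan if tok == "NA" else float(tok)
    values = np.array([by_aa[aa] for aa in AMINO_ACIDS])
    return AAindexEntry(
        accession=accession, description=" ".join(description_parts), values=values
    )


def correlate_propensities(
    propensities: Mapping[str, float] | Sequence[float] | np.ndarray,
    entries: Sequence[AAindexEntry],
    candidate_cutoff: float = 0.5,
) -> list[CorrelationHit]:
    """Pearson R of the propensity vector against every complete entry.

    Results are sorted by |R| descending (ties by accession); entries
    flagged ``candidate`` when |R| exceeds the cutoff.  Incomplete and
    zero-variance entries are skipped with a log note.
    """
    prop = _as_aa_vector(propensities)
    if np.ptp(prop) == 0:
        raise ValueError("propensities have zero variance")
    hits: list[CorrelationHit] = []
    for entry in entries:
        if not entry.complete:
            logger.info("skipping incomplete entry %s", entry.accession)
            continue
        if np.ptp(entry.values) == 0:
            logger.info("skipping zero-variance entry %s", entry.accession)
            continue
        hits.append(_make_hit(entry.accession, pearson_r(prop, entry.values), candidate_cutoff))
    hits.sort(key=lambda h: (-abs(h.r), h.accession))
    return hits


def subset_composition_sum(
    composition: CompositionVector | Mapping[str, float], residues: Sequence[str]
) -> float:
    """Sum of the composition entries for a residue subset (same scale as input)."""
    for aa in residues:
        if aa not in AA_INDEX:
            raise ValueError(f"unknown residue letter {aa!r}")
    return float(sum(composition[aa] for aa in residues))


def mean_sequence_property(record: ProteinRecord, entry: AAindexEntry) -> float:
    """Mean of the per-residue property values over the sequence."""
    if not entry.complete:
        raise ValueError(f"entry {entry.accession} has missing values")
    return float(np.mean([entry.value(aa) for aa in record.sequence]))


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison of mean per-sequence property values."""

    mean_a: float
    mean_b: float
    u: float
    p: float


def compare_group_property(
    group_a: Sequence[ProteinRecord],
    group_b: Sequence[ProteinRecord],
    entry: AAindexEntry,
) -> GroupComparison:
    """Group means of the per-sequence property plus a rank-sum test."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    values_a = [mean_sequence_property(r, entry) for r in group_a]
    values_b = [mean_sequence_property(r, entry) for r in group_b]
    u, p = mann_whitney(values_a, values_b)
    return GroupComparison(
        mean_a=float(np.mean(values_a)), mean_b=float(np.mean(values_b)), u=u, p=p
    )


def score_vs_table_correlation(
    aa_scores: Mapping[str, float] | Sequence[float] | np.ndarray,
    table: Mapping[str, float],
) -> float:
    """Pearson R between 20 per-residue scores and a per-residue value table."""
    scores = _as_aa_vector(aa_scores)
    missing = [aa for aa in AMINO_ACIDS if aa not in table]
    if missing:
        raise ValueError(f"table missing amino acid(s): {''.join(missing)}")
    values = np.array([float(table[aa]) for aa in AMINO_ACIDS])
    return pearson_r(scores, values)


def _as_aa_vector(values) -> np.ndarray:
    """Coerce a mapping or 20-sequence to an alphabetical residue vector."""
    if isinstance(values, Mapping):
        missing = [aa for aa in AMINO_ACIDS if aa not in values]
        if missing:
            raise ValueError(f"missing amino acid(s): {''.join(missing)}")
        return np.array([float(values[aa]) for aa in AMINO_ACIDS])
    if isinstance(values, CompositionVector):
        if values.kind != "AAC":
            raise ValueError("need an AAC-20 composition vector")
        return values.values
    arr = np.asarray(values, dtype=float)
    if arr.shape != (20,):
        raise ValueError(f"expected 20 values, got shape {arr.shape}")
    return arr
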