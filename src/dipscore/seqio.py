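"""Reading, validating, and featurizing protein sequences.

Sequences use the 20 standard one-letter amino-acid codes.  Features are
amino-acid composition (AAC, 20 values) and dipeptide composition (DPC,
400 values over the overlapping adjacent residue pairs).  All vectorized
operations use a fixed alphabetical ordering of residues and dipeptides
(``AMINO_ACIDS`` / ``DIPEPTIDES``).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard residues, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: The 400 ordered dipeptides, alphabetical ("AA", "AC", ..., "YY").
DIPEPTIDES: tuple[str, ...] = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
DIPEPTIDE_INDEX: dict[str, int] = {dp: i for i, dp in enumerate(DIPEPTIDES)}

_VALID_SET = frozenset(AMINO_ACIDS)


class InvalidSequenceError(ValueError):
    """A sequence contains a non-standard letter or is too short."""

    def __init__(self, message: str, record_id: str = "", offending: str = ""):
        super().__init__(message)
        self.record_id = record_id
        self.offending = offending


@dataclass(frozen=True)
class ProteinRecord:
    """An identifier plus a validated amino-acid sequence.

    Lower-case letters are upper-cased before validation.  Sequences must
    be at least two residues long (so a dipeptide exists) and contain only
    the 20 standard codes; anything else (B, J, O, U, X, Z, ``*``, gaps)
    raises :class:`InvalidSequenceError`.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 2:
            raise InvalidSequenceError(
                f"record {self.id!r}: sequence length {len(seq)} < 2",
                record_id=self.id,
            )
        bad = set(seq) - _VALID_SET
        if bad:
            ch = sorted(bad)[0]
            raise InvalidSequenceError(
                f"record {self.id!r}: invalid character {ch!r}",
                record_id=self.id,
                offending=ch,
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CompositionVector:
    """A non-negative frequency vector summing to 1.

    ``kind`` is ``"AAC"`` (20 amino-acid frequencies) or ``"DPC"``
    (400 dipeptide frequencies); ``values`` follows the fixed alphabetical
    ordering.  Supports mapping-style access by residue or dipeptide.
    """

    kind: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        expected = {"AAC": 20, "DPC": 400}
        if self.kind not in expected:
            raise ValueError(f"kind must be 'AAC' or 'DPC', got {self.kind!r}")
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (expected[self.kind],):
            raise ValueError(
                f"{self.kind} vector must have {expected[self.kind]} entries, "
                f"got shape {vals.shape}"
            )
        if np.any(vals < 0):
            raise ValueError("composition values must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"composition must sum to 1, got {vals.sum()!r}")

    def __getitem__(self, key: str) -> float:
        idx = AA_INDEX if self.kind == "AAC" else DIPEPTIDE_INDEX
        return float(self.values[idx[key]])

    def keys(self) -> Sequence[str]:
        return AMINO_ACIDS if self.kind == "AAC" else DIPEPTIDES

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in zip(self.keys(), self.values)}


class FastaResult(list):
    """Records read from a FASTA file, plus the ids skipped under policy='skip'."""

    def __init__(self, records: Iterable[ProteinRecord], skipped: list[tuple[str, str]]):
        super().__init__(records)
        #: ``(record_id, reason)`` pairs for records dropped by policy="skip".
        self.skipped = skipped

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


def read_fasta(
    path: str | Path, policy: str = "reject", allow_empty: bool = False
) -> FastaResult:
    """Read protein records from a FASTA file.

    Parameters
    ----------
    path:
        FASTA file; multi-line sequences allowed, text after the first
        whitespace on a header line is ignored for the id.
    policy:
        ``"reject"`` raises on the first invalid record, naming the
        offending id and character; ``"skip"`` drops invalid records and
        counts them in :attr:`FastaResult.skipped`.

    Returns records in file order.  Raises ``FileNotFoundError`` for a
    missing file and ``ValueError`` for a file with no records.
    """
    if policy not in ("reject", "skip"):
        raise ValueError(f"policy must be 'reject' or 'skip', got {policy!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such FASTA file: {path}")
    records: list[ProteinRecord] = []
    skipped: list[tuple[str, str]] = []
    n_seen = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_seen += 1
        try:
            records.append(ProteinRecord(rec.id, str(rec.seq)))
        except InvalidSequenceError as exc:
            if policy == "reject":
                raise
            skipped.append((rec.id, str(exc)))
    if n_seen == 0 and not allow_empty:
        raise ValueError(f"FASTA file contains no records: {path}")
    if skipped:
        logger.info("read_fasta: skipped %d invalid record(s) in %s", len(skipped), path)
    return FastaResult(records, skipped)


def dipeptide_counts(sequence: str) -> np.ndarray:
    """Integer counts of the L-1 overlapping dipeptides, in DIPEPTIDES order."""
    if len(sequence) < 2:
        raise InvalidSequenceError(f"need length >= 2 for dipeptides, got {len(sequence)}")
    idx = np.fromiter((AA_INDEX[c] for c in sequence), dtype=np.intp, count=len(sequence))
    pair_idx = idx[:-1] * 20 + idx[1:]
    return np.bincount(pair_idx, minlength=400)


def amino_acid_counts(sequence: str) -> np.ndarray:
    """Integer residue counts in AMINO_ACIDS order."""
    if not sequence:
        raise InvalidSequenceError("empty sequence")
    idx = np.fromiter((AA_INDEX[c] for c in sequence), dtype=np.intp, count=len(sequence))
    return np.bincount(idx, minlength=20)


def dipeptide_composition(record: ProteinRecord) -> CompositionVector:
    """400-element dipeptide frequency vector (counts over L-1 pairs, normalized)."""
    counts = dipeptide_counts(record.sequence)
    return CompositionVector("DPC", counts / counts.sum())


def amino_acid_composition(record: ProteinRecord) -> CompositionVector:
    """20-element residue frequency vector."""
    counts = amino_acid_counts(record.sequence)
    return CompositionVector("AAC", counts / counts.sum())


def dpc_matrix(records: Sequence[ProteinRecord]) -> np.ndarray:
    """Stack per-record DPC vectors into an (n, 400) matrix."""
    return np.vstack([dipeptide_composition(r).values for r in records])


def dipeptide_count_matrix(
    records: Sequence[ProteinRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """Integer dipeptide counts per record plus row totals.

    Scoring through counts (``(C @ s) / totals``) rather than
    pre-normalized frequencies keeps a constant card's sequence scores
    exactly constant, so exact rank statistics see genuine ties.
    """
    C = np.vstack([dipeptide_counts(r.sequence) for r in records]).astype(float)
    return C, C.sum(axis=1)


def pooled_composition(
    records: Sequence[ProteinRecord],
    kind: str = "DPC",
    average: str = "pooled",
) -> CompositionVector:
    """Class-level composition over a set of records.

    ``average="pooled"`` (default) divides the summed counts over all
    sequences by the total count — the convention used when compositions
    are reported over all residues of a class.  ``average="per_sequence"``
    instead averages the per-record frequency vectors, weighting every
    sequence equally regardless of length.
    """
    if not records:
        raise ValueError("no records given")
    if average not in ("pooled", "per_sequence"):
        raise ValueError(f"average must be 'pooled' or 'per_sequence', got {average!r}")
    counter = dipeptide_counts if kind == "DPC" else amino_acid_counts
    if average == "pooled":
        total = sum(counter(r.sequence) for r in records)
        return CompositionVector(kind, total / total.sum())
    comps = [counter(r.sequence) for r in records]
    freqs = np.vstack([c / c.sum() for c in comps]).mean(axis=0)
    return CompositionVector(kind, freqs / freqs.sum())


def read_label_table(path: str | Path) -> dict[str, bool]:
    """Read a two-column tab-separated ``id<TAB>label`` table.

    Labels ``pos``/``1`` map to True, ``neg``/``0`` to False.
    """
    labels: dict[str, bool] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rec_id, raw = line.split("\t")
        if raw in ("pos", "1"):
            labels[rec_id] = True
        elif raw in ("neg", "0"):
            labels[rec_id] = False
        else:
            raise ValueError(f"unrecognized label {raw!r} for id {rec_id!r}")
    return labels
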