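"""Synthetic two-class sequence datasets and packaged reference tables.

The generator draws negative-class sequences i.i.d. from a background
residue distribution; positive-class sequences follow the same process
except that at each emission step, with probability ``beta``, one of the
enriched dipeptides is emitted as the next two residues.  The signal is
therefore genuinely dipeptide-level: single-residue composition shifts
are a side effect only of the enriched pairs themselves.

The reference tables bundle printed per-amino-acid values (propensity
scores with class compositions, three physicochemical property scales,
and mean C-alpha B-factors) used by the analysis layer and the test
suite; each loads as a DataFrame indexed alphabetically by residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from dipscore.seqio import AMINO_ACIDS, DIPEPTIDE_INDEX, ProteinRecord

#: Natural residue frequencies (SwissProt-style background), alphabetical.
NATURAL_BACKGROUND: dict[str, float] = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0591, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0393, "R": 0.0553,
    "S": 0.0665, "T": 0.0536, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


def _uniform_background() -> np.ndarray:
    return np.full(20, 0.05)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-class generator.

    ``beta`` is the per-step probability that a positive-class sequence
    emits an enriched dipeptide instead of a single background residue.
    """

    n_pos: int = 100
    n_neg: int = 100
    length_min: int = 100
    length_max: int = 300
    background: np.ndarray = field(default_factory=_uniform_background, repr=False)
    enriched_dipeptides: tuple[str, ...] = ("CP", "CH", "FF", "WH", "PM")
    beta: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        object.__setattr__(self, "enriched_dipeptides", tuple(self.enriched_dipeptides))
        if bg.shape != (20,) or np.any(bg < 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 20 non-negative values summing to 1")
        if not 0.0 <= self.beta <= 0.5:
            raise ValueError("beta must lie in [0, 0.5]")
        if self.length_min < 10 or self.length_max < self.length_min:
            raise ValueError("need 10 <= length_min <= length_max")
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("counts must be non-negative")
        if self.beta > 0 and not self.enriched_dipeptides:
            raise ValueError("beta > 0 requires a non-empty enriched set")
        for dp in self.enriched_dipeptides:
            if dp not in DIPEPTIDE_INDEX:
                raise ValueError(f"not a valid dipeptide: {dp!r}")

    @classmethod
    def with_natural_background(cls, **kwargs) -> "SyntheticSpec":
        bg = np.array([NATURAL_BACKGROUND[aa] for aa in AMINO_ACIDS])
        return cls(background=bg / bg.sum(), **kwargs)


def _draw_sequence(
    rng: np.random.Generator,
    length: int,
    background: np.ndarray,
    enriched: tuple[str, ...],
    beta: float,
) -> str:
    aa = AMINO_ACIDS
    chunks: list[str] = []
    n = 0
    while n < length:
        if beta > 0 and rng.random() < beta:
            chunk = enriched[rng.integers(len(enriched))]
        else:
            chunk = aa[rng.choice(20, p=background)]
        chunks.append(chunk)
        n += len(chunk)
    return "".join(chunks)[:length]


def generate_dataset(spec: SyntheticSpec) -> tuple[list[ProteinRecord], np.ndarray]:
    """Generate labeled records; deterministic for a fixed spec and seed.

    Positives come first (ids ``pos_0001`` ...), then negatives
    (``neg_0001`` ...).  Returns ``(records, labels)`` with a boolean
    label array (True = positive class).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    for i in range(spec.n_pos):
        length = int(rng.integers(spec.length_min, spec.length_max + 1))
        seq = _draw_sequence(rng, length, spec.background, spec.enriched_dipeptides, spec.beta)
        records.append(ProteinRecord(f"pos_{i + 1:04d}", seq))
    for i in range(spec.n_neg):
        length = int(rng.integers(spec.length_min, spec.length_max + 1))
        seq = _draw_sequence(rng, length, spec.background, (), 0.0)
        records.append(ProteinRecord(f"neg_{i + 1:04d}", seq))
    labels = np.array([True] * spec.n_pos + [False] * spec.n_neg, dtype=bool)
    return records, labels


def write_dataset(
    records: Sequence[ProteinRecord],
    labels: Sequence[bool],
    fasta_path: str | Path,
    label_path: str | Path | None = None,
) -> None:
    """Write records as FASTA (60-column wrap) plus an id->label TSV."""
    lines = []
    for rec in records:
        lines.append(f">{rec.id}")
        for i in range(0, len(rec.sequence), 60):
            lines.append(rec.sequence[i : i + 60])
    Path(fasta_path).write_text("\n".join(lines) + "\n")
    if label_path is not None:
        rows = [
            f"{rec.id}\t{'pos' if lab else 'neg'}"
            for rec, lab in zip(records, labels)
        ]
        Path(label_path).write_text("\n".join(rows) + "\n")


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("dipscore.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df = df.set_index("aa").sort_index()
    assert list(df.index) == list(AMINO_ACIDS)
    return df


def propensity_composition_table() -> pd.DataFrame:
    """Reference per-residue propensity scores and class compositions (%).

    Columns: ``score``, ``comp_pos``, ``comp_neg``; index is the residue
    one-letter code, alphabetical.
    """
    return _load_table("aa_propensity_composition.tsv")


def propensity_property_table() -> pd.DataFrame:
    """Reference propensity scores with three property scales.

    Columns: ``score``, ``snep660103`` (aromaticity principal component),
    ``takk010101`` (side-chain stability contribution, kJ/mol),
    ``karp850101`` (flexibility parameter).
    """
    return _load_table("aa_propensity_properties.tsv")


def propensity_bfactor_table() -> pd.DataFrame:
    """Reference propensity scores with mean C-alpha B-factors per class.

    Columns: ``score``, ``bfactor_pos_mean``, ``bfactor_pos_sd``,
    ``bfactor_neg_mean``, ``bfactor_neg_sd``.
    """
    return _load_table("aa_propensity_bfactors.tsv")


def packaged_aaindex_path() -> Path:
    """Path to the packaged AAindex1 excerpt (three real scales plus one
    deliberately incomplete synthetic record)."""
    return Path(str(resources.files("dipscore.data").joinpath("aaindex_excerpt.txt")))
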