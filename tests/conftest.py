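import numpy as np
import pytest

from dipscore.seqio import ProteinRecord
from dipscore.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dataset():
    """60 sequences (30+30) with a strong dipeptide enrichment signal."""
    spec = SyntheticSpec(
        n_pos=30, n_neg=30, length_min=60, length_max=90, beta=0.08, seed=7
    )
    return generate_dataset(spec)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(name, entries):
        lines = []
        for rec_id, seq in entries:
            lines.append(f">{rec_id}")
            lines.append(seq)
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


def random_record(rng, length=50, rec_id="r") -> ProteinRecord:
    from dipscore.seqio import AMINO_ACIDS

    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ProteinRecord(rec_id, seq)
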