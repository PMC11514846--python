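import random

import pytest

from genolaws.fasta_io import GenomeRecord


@pytest.fixture
def fasta_file(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def _write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def random_records():
    """Seeded random ACGT records for round-trip style tests."""
    rng = random.Random(20240830)
    return [
        GenomeRecord(
            id=f"rec{i}",
            sequence="".join(rng.choices("ACGT", k=rng.randint(1, 300))),
            description=f"synthetic record {i}",
        )
        for i in range(5)
    ]
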