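import random

import pytest

from alncat.core import Alignment, SequenceRecord


def make_alignment(rows: dict[str, str], source: str = "test") -> Alignment:
    """Build an alignment from a name->residues dict (insertion order)."""
    return Alignment(
        [SequenceRecord(name, seq) for name, seq in rows.items()], source=source
    )


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20140081)
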