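"""Parsimony-informative site classification and extraction.

A column is parsimony-informative when it contains at least two
distinct character states, each occurring at least twice.  Only
concrete states count: gaps, missing data, ambiguity codes, and stop
characters are excluded — they cannot support a split under parsimony.
"""

from __future__ import annotations

from collections import Counter

from .core import AA_STANDARD, Alignment, SeqType, SequenceRecord

#: minimum number of distinct states and minimum count per state
MIN_STATES = 2
MIN_STATE_COUNT = 2

_NT_STATES = frozenset("ACGTU")


def _informative_states(column: list[str], seqtype: SeqType) -> Counter:
    allowed = _NT_STATES if seqtype is SeqType.NUCLEOTIDE else AA_STANDARD
    counts: Counter = Counter()
    for c in column:
        c = c.upper()
        if c == "U":
            c = "T"  # the RNA and DNA states are the same character state
        if c in allowed:
            counts[c] += 1
    return counts


def is_parsimony_informative(column: list[str], seqtype: SeqType) -> bool:
    """Whether one alignment column is parsimony-informative."""
    counts = _informative_states(column, seqtype)
    qualifying = sum(1 for n in counts.values() if n >= MIN_STATE_COUNT)
    return qualifying >= MIN_STATES


def extract_informative(alignment: Alignment) -> tuple[Alignment | None, list[int]]:
    """Extract the parsimony-informative columns of an alignment.

    Returns the sub-alignment of informative columns (in original
    order) and their 1-based indices.  When no column qualifies the
    alignment is ``None`` and the index list empty — an allowed,
    reported outcome rather than an error.
    """
    seqtype = alignment.alignment_seqtype
    indices = [
        i + 1
        for i in range(alignment.length)
        if is_parsimony_informative(alignment.column(i), seqtype)
    ]
    if not indices:
        return None, []
    # records are built without re-validation: supermatrix rows can mix
    # alphabets (nucleotide + amino acid + structure pads)
    records = []
    for rec in alignment:
        sub_rec = SequenceRecord.__new__(SequenceRecord)
        sub_rec.name = rec.name
        sub_rec.residues = "".join(rec.residues[i - 1] for i in indices)
        sub_rec.seqtype = rec.seqtype
        records.append(sub_rec)
    sub = Alignment.__new__(Alignment)
    sub.records = records
    sub.source = alignment.source
    sub.alignment_seqtype = seqtype
    return sub, indices
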