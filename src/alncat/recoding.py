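"""RY recoding and third-codon-position exclusion.

RY coding collapses nucleotides into purines (A, G -> R) and
pyrimidines (C, T, U -> Y), removing compositional signal that can
mislead tree reconstruction.  It can be applied to whole sequences or
to third codon positions only; alternatively third positions can be
dropped outright.  Both third-position operations assume in-frame
(frame +1) protein-coding input — columns 3, 6, 9, ... (1-based).
"""

from __future__ import annotations

from enum import Enum

from .core import Alignment, InvalidInputError, SeqType, SequenceRecord
from .translation import AMBIGUITY_MAP

_PURINES = frozenset("AGR")
_PYRIMIDINES = frozenset("CTUY")


class RyMode(Enum):
    ALL = "all"
    THIRD_POSITIONS = "third"


def ry_encode_char(c: str) -> str:
    """RY-encode one nucleotide character.

    Purines give R, pyrimidines Y; ``-`` and ``?`` are preserved.
    Ambiguity codes spanning both classes (W, S, K, M, B, D, H, V, N)
    have no unique R/Y image and become ``?``.
    """
    c = c.upper()
    if c in "-?":
        return c
    if c in _PURINES:
        return "R"
    if c in _PYRIMIDINES:
        return "Y"
    if c in AMBIGUITY_MAP:
        return "?"
    raise InvalidInputError(f"illegal nucleotide character {c!r}")


def ry_encode(alignment: Alignment, mode: RyMode = RyMode.ALL) -> Alignment:
    """RY-encode a nucleotide alignment; length is unchanged.

    ``THIRD_POSITIONS`` recodes only columns 3, 6, 9, ... (1-based).
    Amino-acid and structure alignments pass through unchanged.
    """
    if alignment.alignment_seqtype is not SeqType.NUCLEOTIDE:
        return alignment
    records = []
    for rec in alignment:
        if mode is RyMode.ALL:
            encoded = "".join(ry_encode_char(c) for c in rec.residues)
        else:
            encoded = "".join(
                ry_encode_char(c) if (i + 1) % 3 == 0 else c
                for i, c in enumerate(rec.residues)
            )
        records.append(SequenceRecord(rec.name, encoded, SeqType.NUCLEOTIDE))
    return Alignment(records, source=alignment.source)


def exclude_third_positions(alignment: Alignment) -> Alignment:
    """Drop columns 3, 6, 9, ... (1-based) from a nucleotide alignment.

    Output length is ``L - L // 3``.  Non-nucleotide alignments pass
    through unchanged.
    """
    if alignment.alignment_seqtype is not SeqType.NUCLEOTIDE:
        return alignment
    if alignment.length < 3:
        return alignment
    records = [
        SequenceRecord(
            rec.name,
            "".join(c for i, c in enumerate(rec.residues) if (i + 1) % 3 != 0),
            SeqType.NUCLEOTIDE,
        )
        for rec in alignment
    ]
    return Alignment(records, source=alignment.source)
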