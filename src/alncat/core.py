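"""Domain model: sequence records, alignments, and sequence-type detection.

Every processing stage in :mod:`alncat` operates on :class:`Alignment`
objects — ordered, equal-length collections of named sequences from one
input file.  Three kinds of sequence are distinguished: nucleotide
(DNA/RNA with IUPAC ambiguity codes), amino acid, and dot-bracket
secondary-structure strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator


class SeqType(Enum):
    """Kind of data a sequence carries."""

    NUCLEOTIDE = "nucleotide"
    AMINO_ACID = "amino_acid"
    STRUCTURE = "structure"


#: Concrete nucleotide states plus N (fully ambiguous).
NT_CORE = frozenset("ACGTUN")
#: Partial IUPAC ambiguity codes.
NT_AMBIGUITY = frozenset("RYSWKMBDHV")
NT_ALPHABET = NT_CORE | NT_AMBIGUITY | frozenset("-?")

AA_STANDARD = frozenset("ACDEFGHIKLMNPQRSTVWY")
AA_ALPHABET = AA_STANDARD | frozenset("BZJX*-?")

STRUCTURE_ALPHABET = frozenset("().-?")

#: Characters that carry no state information in any alphabet.
GAP_CHARS = frozenset("-?")

ALPHABETS = {
    SeqType.NUCLEOTIDE: NT_ALPHABET,
    SeqType.AMINO_ACID: AA_ALPHABET,
    SeqType.STRUCTURE: STRUCTURE_ALPHABET,
}

#: Fraction of informative characters that must be A/C/G/T/U/N for a
#: sequence to be classified as nucleotide.  Chosen to tolerate rare
#: ambiguity codes without misclassifying protein sequences.
NUCLEOTIDE_FRACTION = 0.95


class AlncatError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(AlncatError):
    """A value violates an operation's preconditions."""


class ConsistencyError(AlncatError):
    """Inputs are individually valid but mutually inconsistent."""


def detect_seqtype(residues: str) -> SeqType:
    """Classify a residue string as nucleotide, amino acid, or structure.

    Detection is case-insensitive and applies a fixed priority order:
    a string whose informative characters are all ``(``, ``)`` or ``.``
    is a structure string; otherwise, if at least 95% of the non-gap,
    non-``?`` characters are A/C/G/T/U/N the string is nucleotide;
    anything else is amino acid.  The priority order matters because
    every nucleotide string is also a character-wise legal protein
    string.

    Raises
    ------
    InvalidInputError
        If *residues* is empty.
    """
    if not residues:
        raise InvalidInputError("cannot detect sequence type of an empty string")
    upper = residues.upper()
    non_gap = [c for c in upper if c != "-"]
    if non_gap and all(c in "()." for c in non_gap):
        return SeqType.STRUCTURE
    informative = [c for c in upper if c not in GAP_CHARS]
    if not informative:
        # all gaps/missing: call it nucleotide, the least restrictive choice
        return SeqType.NUCLEOTIDE
    nt_like = sum(1 for c in informative if c in NT_CORE)
    if nt_like / len(informative) >= NUCLEOTIDE_FRACTION:
        return SeqType.NUCLEOTIDE
    return SeqType.AMINO_ACID


@dataclass
class SequenceRecord:
    """One named, aligned sequence with a detected sequence type.

    Residues are upper-cased on construction; ``U`` is preserved as-is.
    If *seqtype* is not given it is detected from the residues.
    """

    name: str
    residues: str
    seqtype: SeqType | None = None

    def __post_init__(self) -> None:
        if not self.name or "\n" in self.name:
            raise InvalidInputError(f"invalid sequence name: {self.name!r}")
        if not self.residues:
            raise InvalidInputError(f"sequence {self.name!r} has no residues")
        self.residues = self.residues.upper()
        if self.seqtype is None:
            self.seqtype = detect_seqtype(self.residues)
        alphabet = ALPHABETS[self.seqtype]
        bad = set(self.residues) - alphabet
        if bad:
            raise InvalidInputError(
                f"sequence {self.name!r}: characters {sorted(bad)} are not legal "
                f"for {self.seqtype.value} data"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """An equal-length, uniquely-named set of sequence records.

    ``alignment_seqtype`` is the type shared by all non-structure
    records; files mixing nucleotide and amino-acid records are
    rejected.  A file of only structure strings has type STRUCTURE.

    Length and name-uniqueness invariants are checked by
    :func:`validate_alignment` rather than at construction time, so
    that violations can be reported rather than thrown; the file
    readers call it and refuse invalid input.
    """

    records: list[SequenceRecord]
    source: str = "<memory>"
    alignment_seqtype: SeqType = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise InvalidInputError(f"{self.source}: alignment has no sequences")
        non_structure = {
            r.seqtype for r in self.records if r.seqtype is not SeqType.STRUCTURE
        }
        if len(non_structure) > 1:
            raise ConsistencyError(
                f"{self.source}: mixes nucleotide and amino-acid sequences in one file"
            )
        self.alignment_seqtype = (
            non_structure.pop() if non_structure else SeqType.STRUCTURE
        )

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def get(self, name: str) -> SequenceRecord | None:
        for r in self.records:
            if r.name == name:
                return r
        return None

    def column(self, i: int) -> list[str]:
        """0-based column *i* as a list of characters, one per record."""
        return [r.residues[i] for r in self.records]


def _alignment_violations(records: Iterable[SequenceRecord], source: str) -> list[str]:
    violations: list[str] = []
    records = list(records)
    if not records:
        return [f"{source}: alignment has no sequences"]
    length = len(records[0].residues)
    seen: set[str] = set()
    for r in records:
        if len(r.residues) != length:
            violations.append(
                f"{source}: sequence {r.name!r} has length {len(r.residues)}, "
                f"expected {length}"
            )
        if r.name in seen:
            violations.append(f"{source}: duplicate sequence name {r.name!r}")
        seen.add(r.name)
    return violations


def validate_alignment(alignment: Alignment) -> list[str]:
    """Return a list of invariant violations (empty when valid).

    Violations are reported, never raised: each entry names the
    offending record and the broken rule.
    """
    return _alignment_violations(alignment.records, alignment.source)
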