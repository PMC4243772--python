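"""Codon translation with IUPAC ambiguity resolution, and reverse
translation of amino acids to compressed IUPAC codons.

Forward translation expands every ambiguity code in a triplet into its
set of concrete bases, forms all concrete codons, and emits the amino
acid only when every concrete codon agrees (``YTR`` -> L, because TTA,
TTG, CTA, and CTG are all leucine); otherwise ``?`` (``RCT`` covers
both threonine and alanine).  Reverse translation compresses the codon
set of an amino acid position-wise into IUPAC codes (lossy: L ->
``YTN`` also covers phenylalanine codons).

The standard genetic code (Biopython table 1) is used throughout;
translation is always in frame +1 — reading frames are taken as given,
never inferred.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

from Bio.Data.CodonTable import standard_dna_table

from .core import Alignment, InvalidInputError, SeqType, SequenceRecord

#: IUPAC nucleotide character -> set of concrete bases (U reads as T).
AMBIGUITY_MAP: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: the unique inverse of AMBIGUITY_MAP, keyed by frozen base set
IUPAC_FROM_SET: dict[frozenset[str], str] = {
    bases: code for code, bases in AMBIGUITY_MAP.items() if code != "U"
}

#: codon -> amino acid over all 64 concrete codons, stops as '*'
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TABLE.update({codon: "*" for codon in standard_dna_table.stop_codons})

#: amino acid -> tuple of concrete codons
CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    CODONS_FOR_AA.setdefault(_aa, ())
    CODONS_FOR_AA[_aa] += (_codon,)
# B = D or N, Z = E or Q, J = I or L: union of the member codon sets
CODONS_FOR_AA["B"] = CODONS_FOR_AA["D"] + CODONS_FOR_AA["N"]
CODONS_FOR_AA["Z"] = CODONS_FOR_AA["E"] + CODONS_FOR_AA["Q"]
CODONS_FOR_AA["J"] = CODONS_FOR_AA["I"] + CODONS_FOR_AA["L"]


def translate_codon(triplet: str) -> str:
    """Translate one (possibly ambiguous) nucleotide triplet.

    Rules, in order: an incomplete triplet (fewer than three
    characters) is ``?``; a triplet of three gaps is ``-``; a triplet
    mixing gaps with bases is ``?``; otherwise every ambiguity code
    (``?`` counts as fully ambiguous, like N) is expanded and the
    amino acid is returned iff all concrete codons in the expansion
    agree, else ``?``.  Stop codons give ``*``; expansions mixing stop
    and sense codons give ``?``.
    """
    triplet = triplet.upper()
    for c in triplet:
        if c not in AMBIGUITY_MAP and c not in "-?":
            raise InvalidInputError(f"illegal nucleotide character {c!r}")
    if len(triplet) < 3:
        return "?"
    if triplet == "---":
        return "-"
    if "-" in triplet:
        return "?"
    return _translate_complete(triplet)


@lru_cache(maxsize=None)
def _translate_complete(triplet: str) -> str:
    expansions = [
        AMBIGUITY_MAP["N"] if c == "?" else AMBIGUITY_MAP[c] for c in triplet
    ]
    amino_acids = {
        CODON_TABLE["".join(codon)] for codon in product(*expansions)
    }
    if len(amino_acids) == 1:
        return amino_acids.pop()
    return "?"


def translate_record(record: SequenceRecord) -> tuple[SequenceRecord, bool]:
    """Translate one nucleotide record in frame +1.

    Returns the amino-acid record and whether the residue length was
    not a multiple of three (a trailing incomplete triplet, emitted as
    an extra ``?`` column).
    """
    seq = record.residues
    incomplete = len(seq) % 3 != 0
    chars = [translate_codon(seq[i : i + 3]) for i in range(0, len(seq), 3)]
    return (
        SequenceRecord(record.name, "".join(chars), SeqType.AMINO_ACID),
        incomplete,
    )


def translate_nt_to_aa(alignment: Alignment) -> tuple[Alignment, list[str]]:
    """Translate a nucleotide alignment codon-wise to amino acids.

    Output length is ``L // 3``, plus one ``?`` column when ``L`` is
    not a multiple of three; in that case a warning is returned.
    Non-nucleotide alignments pass through untouched — only suitable
    input is translated, so mixed nucleotide/protein file sets can be
    processed in one run.
    """
    if alignment.alignment_seqtype is not SeqType.NUCLEOTIDE:
        return alignment, []
    warnings: list[str] = []
    translated = []
    incomplete_any = False
    for rec in alignment:
        new_rec, incomplete = translate_record(rec)
        incomplete_any = incomplete_any or incomplete
        translated.append(new_rec)
    if incomplete_any:
        warnings.append(
            f"{alignment.source}: sequence length {alignment.length} is not a "
            "multiple of three; trailing incomplete triplets translated to '?'"
        )
    return Alignment(translated, source=alignment.source), warnings


@lru_cache(maxsize=None)
def reverse_translate_aa(aa: str) -> str:
    """Reverse-translate one amino acid to a compressed IUPAC triplet.

    At each codon position the IUPAC code for the union of bases seen
    across all of the amino acid's codons is emitted (M -> ``ATG``,
    L -> ``YTN``).  ``-`` maps to ``---``; ``?`` and ``X`` map to
    ``NNN``.
    """
    aa = aa.upper()
    if aa == "-":
        return "---"
    if aa in "?X":
        return "NNN"
    codons = CODONS_FOR_AA.get(aa)
    if codons is None:
        raise InvalidInputError(f"unknown amino-acid character {aa!r}")
    return "".join(
        IUPAC_FROM_SET[frozenset(codon[pos] for codon in codons)] for pos in range(3)
    )


def reverse_translate_alignment(alignment: Alignment) -> Alignment:
    """Reverse-translate an amino-acid alignment to IUPAC nucleotides.

    Output length is three times the input length.  Nucleotide
    alignments pass through untouched.
    """
    if alignment.alignment_seqtype is not SeqType.AMINO_ACID:
        return alignment
    records = [
        SequenceRecord(
            rec.name,
            "".join(reverse_translate_aa(c) for c in rec.residues),
            SeqType.NUCLEOTIDE,
        )
        for rec in alignment
    ]
    return Alignment(records, source=alignment.source)
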