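"""Codon translation against an independent brute-force oracle.

The oracle expands IUPAC codes with Biopython's ambiguity tables and
translates every concrete codon with ``Bio.Seq.translate``, keeping
the amino acid only when all expansions agree — a completely separate
path from the implementation under test.
"""

from itertools import product

import pytest
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from alncat.core import SeqType
from alncat.translation import (
    AMBIGUITY_MAP,
    CODONS_FOR_AA,
    reverse_translate_aa,
    reverse_translate_alignment,
    translate_codon,
    translate_nt_to_aa,
)
from conftest import make_alignment

AMBIG_CODES = sorted(set(ambiguous_dna_values) - {"X"})  # ACGT + 11 IUPAC codes


def oracle_translate(triplet: str) -> str:
    aas = {
        str(Seq("".join(codon)).translate())
        for codon in product(*(ambiguous_dna_values[c] for c in triplet))
    }
    return aas.pop() if len(aas) == 1 else "?"


@pytest.mark.parametrize(
    "triplet, expected",
    [
        ("YTR", "L"),  # all expansions are leucine
        ("RCT", "?"),  # threonine or alanine: unresolvable
        ("ATG", "M"),
        ("AC", "?"),  # incomplete triplet
        ("GCN", "A"),  # four-fold degenerate alanine
        ("---", "-"),  # pure-gap triplet preserves the indel column
        ("A-G", "?"),  # gap mixed with bases is unresolvable
        ("TAA", "*"),
        ("TRA", "*"),  # TAA and TGA are both stops
        ("TRG", "?"),  # stop (TAG) or tryptophan (TGG): unresolvable
        ("GC?", "A"),  # '?' expands like N
        ("ytr", "L"),  # case-insensitive
    ],
)
def test_translate_codon_examples(triplet, expected):
    assert translate_codon(triplet) == expected


def test_translate_codon_agrees_with_oracle_on_all_ambiguity_triplets():
    for triplet in product(AMBIG_CODES, repeat=3):
        s = "".join(triplet)
        assert translate_codon(s) == oracle_translate(s), s


def test_translate_codon_rejects_illegal_characters():
    from alncat.core import InvalidInputError

    with pytest.raises(InvalidInputError):
        translate_codon("A!G")


def test_translate_alignment_and_length_warning():
    aln = make_alignment({"a": "ATGGCN", "b": "ATGTGG"})
    out, warnings = translate_nt_to_aa(aln)
    assert [r.residues for r in out] == ["MA", "MW"]
    assert warnings == []

    short = make_alignment({"a": "ATGGC"})
    out, warnings = translate_nt_to_aa(short)
    assert out.records[0].residues == "M?"
    assert len(warnings) == 1 and "multiple of three" in warnings[0]


def test_translate_passes_amino_acid_alignments_through():
    aa = make_alignment({"a": "MKLF", "b": "MKIF"})
    out, warnings = translate_nt_to_aa(aa)
    assert out is aa and warnings == []


@pytest.mark.parametrize(
    "aa, expected",
    [("M", "ATG"), ("W", "TGG"), ("L", "YTN"), ("-", "---"), ("?", "NNN"), ("X", "NNN")],
)
def test_reverse_translate_examples(aa, expected):
    assert reverse_translate_aa(aa) == expected


def test_reverse_translation_expansion_covers_all_codons():
    # the compressed triplet must expand to a superset of the amino
    # acid's concrete codons (compression is lossy upward, never down)
    for aa, codons in CODONS_FOR_AA.items():
        compressed = reverse_translate_aa(aa)
        expansion = {
            "".join(c) for c in product(*(AMBIGUITY_MAP[x] for x in compressed))
        }
        assert set(codons) <= expansion, aa


def test_reverse_translate_alignment_and_round_trip():
    protein = make_alignment({"a": "MW-", "b": "MWK"})
    nt = reverse_translate_alignment(protein)
    assert nt.length == 9
    assert nt.records[0].residues == "ATGTGG---"
    # M and W have single codons, so translating back restores them
    back, _ = translate_nt_to_aa(nt)
    assert back.records[0].residues == "MW-"
    assert back.records[1].residues[:2] == "MW"


def test_reverse_translate_passes_nucleotide_through():
    nt = make_alignment({"a": "ACGT"})
    assert reverse_translate_alignment(nt) is nt
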