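import random

import pytest

from alncat.concatenation import (
    concatenate,
    resolve_input_order,
    slice_partition,
)
from alncat.core import ConsistencyError, InvalidInputError, SeqType
from alncat.fixtures import random_alignment
from conftest import make_alignment


def brute_force_cell(alignments, gene_names, taxon, gene):
    """Independent oracle: the expected residues for one (taxon, gene)
    cell, computed straight from the inputs."""
    pad = {SeqType.NUCLEOTIDE: "N", SeqType.AMINO_ACID: "X", SeqType.STRUCTURE: "."}
    aln = alignments[gene_names.index(gene)]
    rec = aln.get(taxon)
    if rec is not None:
        return rec.residues
    return pad[aln.alignment_seqtype] * aln.length


def test_concatenate_worked_example():
    g1 = make_alignment({"a": "ACGT", "b": "ACGA"}, source="g1.fas")
    g2 = make_alignment({"a": "GG", "c": "GC"}, source="g2.fas")
    sm = concatenate([g1, g2])
    assert sm.alignment.names == ["a", "b", "c"]
    assert sm.alignment.get("b").residues == "ACGA" + "NN"
    assert sm.alignment.get("c").residues == "NNNN" + "GC"
    assert [(p.gene_name, p.start, p.end) for p in sm.partitions] == [
        ("g1", 1, 4),
        ("g2", 5, 6),
    ]
    assert sorted(sm.padded) == [("b", "g2"), ("c", "g1")]


def test_single_input_is_identity():
    g = make_alignment({"a": "ACGT", "b": "ACGA"}, source="solo.fas")
    sm = concatenate([g])
    assert sm.alignment.get("a").residues == "ACGT"
    assert [(p.start, p.end) for p in sm.partitions] == [(1, 4)]
    assert sm.padded == []


def test_structure_gene_pads_with_dots():
    nt = make_alignment({"a": "ACGT", "b": "ACGA"}, source="nt.fas")
    ss = make_alignment({"a": "(())"}, source="ss.fas")
    sm = concatenate([nt, ss])
    assert sm.alignment.get("b").residues == "ACGA" + "...."


def test_amino_acid_gene_pads_with_x():
    aa = make_alignment({"a": "MKLF"}, source="aa.fas")
    nt = make_alignment({"a": "ACG", "b": "ACA"}, source="nt.fas")
    sm = concatenate([aa, nt])
    assert sm.alignment.get("b").residues == "XXXX" + "ACA"


def test_empty_input_list_rejected():
    with pytest.raises(InvalidInputError):
        concatenate([])


def test_duplicate_gene_stems_get_suffixes():
    g1 = make_alignment({"a": "AC"}, source="locus.fas")
    g2 = make_alignment({"a": "GT"}, source="locus.phy")
    sm = concatenate([g1, g2])
    assert [p.gene_name for p in sm.partitions] == ["locus", "locus_2"]


def test_column_conservation_and_round_trip(rng):
    """Each partition sliced back out of the supermatrix, with
    fully-padded rows dropped, equals the original gene exactly."""
    for trial in range(30):
        n_taxa = rng.randint(3, 7)
        taxa = [f"t{i}" for i in range(n_taxa)]
        alignments = []
        for g in range(rng.randint(2, 5)):
            present = [t for t in taxa if t == taxa[0] or rng.random() > 0.3]
            seqtype = rng.choice([SeqType.NUCLEOTIDE, SeqType.AMINO_ACID])
            aln = random_alignment(
                rng,
                len(present),
                rng.randint(2, 30),
                seqtype,
                taxa=present,
                source=f"gene{g}.fas",
            )
            alignments.append(aln)
        sm = concatenate(alignments)
        assert sm.length == sum(a.length for a in alignments)
        for part, original in zip(sm.partitions, alignments):
            back = slice_partition(sm, part)
            # row order follows the supermatrix (taxon union order);
            # content must match the original gene exactly
            assert {r.name: r.residues for r in back} == {
                r.name: r.residues for r in original
            }


def test_cell_level_oracle(rng):
    alignments = []
    taxa = ["t1", "t2", "t3", "t4"]
    for g in range(3):
        present = [t for t in taxa if t == "t1" or rng.random() > 0.4]
        alignments.append(
            random_alignment(rng, len(present), 6, taxa=present, source=f"g{g}.fas")
        )
    sm = concatenate(alignments)
    gene_names = [p.gene_name for p in sm.partitions]
    for rec in sm.alignment:
        for p in sm.partitions:
            expected = brute_force_cell(alignments, gene_names, rec.name, p.gene_name)
            assert rec.residues[p.start - 1 : p.end] == expected


def test_row_order_is_first_appearance():
    g1 = make_alignment({"b": "AC", "a": "GT"}, source="g1.fas")
    g2 = make_alignment({"c": "AC", "a": "GT"}, source="g2.fas")
    sm = concatenate([g1, g2])
    assert sm.alignment.names == ["b", "a", "c"]


def test_resolve_input_order(tmp_path):
    for name in ("b.fas", "a.fas"):
        (tmp_path / name).write_text(">x\nAC\n")
    explicit = resolve_input_order([tmp_path / "b.fas", tmp_path / "a.fas"])
    assert [p.name for p in explicit] == ["b.fas", "a.fas"]
    from_dir = resolve_input_order([tmp_path])
    assert [p.name for p in from_dir] == ["a.fas", "b.fas"]
    with pytest.raises(ConsistencyError):
        resolve_input_order([tmp_path / "a.fas", tmp_path / "a.fas"])
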