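"""Deterministic synthetic alignment generation for testing and demos.

The generator emulates a small multi-gene phylogenomic data set: a
panel of taxa, several gene alignments of different lengths and
sequence types (nucleotide, amino acid, optionally dot-bracket
structure), incomplete taxon sampling (some taxa missing from some
genes, as in real supermatrix studies), and a few planted
parsimony-informative columns whose positions are recorded as ground
truth.  Files are emitted in rotating formats (FASTA, PHYLIP, CLUSTAL)
so multi-format reading is exercised by construction.

Everything is driven by one :class:`random.Random` seed; the same seed
always produces byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .core import Alignment, InvalidInputError, SeqType, SequenceRecord
from .io_formats import CLUSTAL, FASTA, OutputOptions, PHYLIP, write_alignment

_NT = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureTruth:
    """Ground truth recorded while generating a fixture set."""

    files: list[Path] = field(default_factory=list)
    taxa: list[str] = field(default_factory=list)
    #: gene name -> Alignment actually written
    alignments: dict[str, Alignment] = field(default_factory=dict)
    #: (taxon, gene) pairs deliberately left out of a gene
    missing: list[tuple[str, str]] = field(default_factory=list)
    #: gene name -> 1-based columns planted to be parsimony-informative
    planted_informative: dict[str, list[int]] = field(default_factory=dict)


def random_balanced_dot_bracket(rng: random.Random, length: int) -> str:
    """A random properly nested dot-bracket string of *length*."""
    chars: list[str] = []
    open_count = 0
    for i in range(length):
        remaining = length - i
        options = []
        if remaining > open_count + 1:
            options.append("(")
        if open_count > 0:
            options.append(")")
        if remaining > open_count:
            options.append(".")
        c = rng.choice(options)
        if c == "(":
            open_count += 1
        elif c == ")":
            open_count -= 1
        chars.append(c)
    return "".join(chars)


def _plant_informative(
    rng: random.Random, rows: dict[str, list[str]], length: int, alphabet: str
) -> list[int]:
    """Overwrite a few columns so they are parsimony-informative by
    construction: two states, each in at least two sequences."""
    taxa = list(rows)
    if len(taxa) < 4 or length < 2:
        return []
    n_plant = min(3, length // 4 + 1)
    columns = rng.sample(range(length), n_plant)
    for col in sorted(columns):
        a, b = rng.sample(alphabet, 2)
        split = rng.randint(2, len(taxa) - 2)
        shuffled = taxa[:]
        rng.shuffle(shuffled)
        for i, taxon in enumerate(shuffled):
            rows[taxon][col] = a if i < split else b
    return sorted(c + 1 for c in columns)


def random_alignment(
    rng: random.Random,
    n_taxa: int,
    length: int,
    seqtype: SeqType = SeqType.NUCLEOTIDE,
    taxa: Sequence[str] | None = None,
    gap_fraction: float = 0.05,
    source: str = "<random>",
) -> Alignment:
    """One random in-memory alignment (no planted structure)."""
    if taxa is None:
        taxa = [f"taxon_{i + 1:02d}" for i in range(n_taxa)]
    records = []
    for name in taxa:
        if seqtype is SeqType.STRUCTURE:
            residues = random_balanced_dot_bracket(rng, length)
        else:
            alphabet = _NT if seqtype is SeqType.NUCLEOTIDE else _AA
            residues = "".join(
                "-" if rng.random() < gap_fraction else rng.choice(alphabet)
                for _ in range(length)
            )
            if set(residues) == {"-"}:  # keep at least one informative state
                residues = rng.choice(alphabet) + residues[1:]
        records.append(SequenceRecord(name, residues, seqtype))
    return Alignment(records, source=source)


def generate_fixture(
    seed: int,
    out_dir: str | Path,
    n_taxa: int = 8,
    n_genes: int = 4,
    lengths: Sequence[int] | None = None,
    seqtype_mix: Sequence[SeqType] | None = None,
    missing_fraction: float = 0.2,
) -> FixtureTruth:
    """Write a multi-gene fixture data set and return its ground truth.

    Parameters
    ----------
    seed
        Seeds a private :class:`random.Random`; identical seeds give
        byte-identical files.
    lengths
        Per-gene alignment lengths; defaults to 30, 45, 60, ... per
        gene (nucleotide lengths are multiples of three so the genes
        read as in-frame coding sequence).
    seqtype_mix
        Per-gene sequence types, cycled; defaults to alternating
        nucleotide and amino acid.
    missing_fraction
        Probability that a given non-anchor taxon is absent from a
        given gene (the first taxon is always present everywhere, so
        every gene keeps at least one sequence).
    """
    if not 0 <= missing_fraction < 1:
        raise InvalidInputError("missing_fraction must be in [0, 1)")
    if n_taxa < 1 or n_genes < 1:
        raise InvalidInputError("n_taxa and n_genes must be positive")
    rng = random.Random(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if lengths is None:
        lengths = [30 + 15 * i for i in range(n_genes)]
    if seqtype_mix is None:
        seqtype_mix = [SeqType.NUCLEOTIDE, SeqType.AMINO_ACID]
    truth = FixtureTruth(taxa=[f"taxon_{i + 1:02d}" for i in range(n_taxa)])
    formats = [FASTA, PHYLIP, CLUSTAL]
    for g in range(n_genes):
        gene = f"gene_{g + 1:02d}"
        seqtype = seqtype_mix[g % len(seqtype_mix)]
        length = lengths[g % len(lengths)]
        present = [
            t
            for i, t in enumerate(truth.taxa)
            if i == 0 or rng.random() >= missing_fraction
        ]
        for t in truth.taxa:
            if t not in present:
                truth.missing.append((t, gene))
        if seqtype is SeqType.STRUCTURE:
            aln = random_alignment(
                rng, len(present), length, seqtype, taxa=present, source=gene
            )
            truth.planted_informative[gene] = []
        else:
            alphabet = _NT if seqtype is SeqType.NUCLEOTIDE else _AA
            rows = {
                t: [
                    "-" if rng.random() < 0.05 else rng.choice(alphabet)
                    for _ in range(length)
                ]
                for t in present
            }
            truth.planted_informative[gene] = _plant_informative(
                rng, rows, length, alphabet
            )
            records = [
                SequenceRecord(t, "".join(rows[t]), seqtype) for t in present
            ]
            aln = Alignment(records, source=gene)
        fmt = formats[g % len(formats)]
        if seqtype is SeqType.STRUCTURE:
            fmt = FASTA  # brackets clash with the other formats' syntax
        if fmt == CLUSTAL:
            path = out_dir / f"{gene}.aln"
            _write_clustal(aln, path)
        else:
            path = write_alignment(
                aln, OutputOptions(formats=(fmt,)), out_dir, base_name=gene
            )[0]
        truth.files.append(path)
        aln.source = path.name
        truth.alignments[gene] = aln
    return truth


def _write_clustal(alignment: Alignment, out: Path) -> None:
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord as BioSeqRecord
    from Bio import AlignIO

    msa = MultipleSeqAlignment(
        [BioSeqRecord(Seq(r.residues), id=r.name, description="") for r in alignment]
    )
    AlignIO.write(msa, str(out), "clustal")
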