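"""Supermatrix concatenation keyed by taxon name.

Per-gene alignments are joined side by side into one matrix.  The
taxon set is the union over all inputs, ordered by first appearance;
a taxon absent from a gene receives a replacement (pad) string of that
gene's length — ``N`` for nucleotide, ``X`` for amino acid, ``.`` for
dot-bracket structure data.  Each gene's 1-based inclusive coordinate
range is recorded in a partition map for downstream model assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .core import (
    Alignment,
    ConsistencyError,
    InvalidInputError,
    SeqType,
    SequenceRecord,
)

PAD_CHAR = {
    SeqType.NUCLEOTIDE: "N",
    SeqType.AMINO_ACID: "X",
    SeqType.STRUCTURE: ".",
}


@dataclass(frozen=True)
class Partition:
    """One gene's span in the supermatrix, 1-based inclusive."""

    gene_name: str
    start: int
    end: int
    seqtype: SeqType

    @property
    def length(self) -> int:
        return self.end - self.start + 1


PartitionMap = list[Partition]


@dataclass
class Supermatrix:
    """A concatenated alignment plus partition coordinates and the
    (taxon, gene) pairs that were padded with replacement strings."""

    alignment: Alignment
    partitions: PartitionMap
    padded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.alignment.length


def _gene_names(alignments: Sequence[Alignment]) -> list[str]:
    # file stem; duplicate stems are disambiguated with a numeric suffix
    names: list[str] = []
    for aln in alignments:
        stem = Path(aln.source).stem or aln.source
        name = stem
        k = 2
        while name in names:
            name = f"{stem}_{k}"
            k += 1
        names.append(name)
    return names


def concatenate(alignments: Sequence[Alignment]) -> Supermatrix:
    """Concatenate per-gene alignments into a supermatrix.

    Taxa are matched by exact name across inputs; the row order is
    first appearance across inputs in input order.  Nucleotide,
    amino-acid, and structure genes may be mixed freely in one
    supermatrix.
    """
    if not alignments:
        raise InvalidInputError("nothing to concatenate: no input alignments")
    gene_names = _gene_names(alignments)
    taxa: list[str] = []
    for aln in alignments:
        for name in aln.names:
            if name not in taxa:
                taxa.append(name)
    partitions: PartitionMap = []
    start = 1
    for gene, aln in zip(gene_names, alignments):
        end = start + aln.length - 1
        partitions.append(Partition(gene, start, end, aln.alignment_seqtype))
        start = end + 1
    padded: list[tuple[str, str]] = []
    rows: dict[str, list[str]] = {t: [] for t in taxa}
    for gene, aln in zip(gene_names, alignments):
        pad = PAD_CHAR[aln.alignment_seqtype] * aln.length
        present = {rec.name: rec.residues for rec in aln}
        for taxon in taxa:
            piece = present.get(taxon)
            if piece is None:
                piece = pad
                padded.append((taxon, gene))
            rows[taxon].append(piece)
    # a mixed-type supermatrix row is typed by its dominant content;
    # bypass per-record alphabet checks by not re-detecting
    records = []
    overall_type = _overall_seqtype(alignments)
    for taxon in taxa:
        residues = "".join(rows[taxon])
        rec = SequenceRecord.__new__(SequenceRecord)
        rec.name = taxon
        rec.residues = residues
        rec.seqtype = overall_type
        records.append(rec)
    alignment = Alignment.__new__(Alignment)
    alignment.records = records
    alignment.source = "supermatrix"
    alignment.alignment_seqtype = overall_type
    return Supermatrix(alignment, partitions, padded)


def _overall_seqtype(alignments: Sequence[Alignment]) -> SeqType:
    types = {a.alignment_seqtype for a in alignments}
    if len(types) == 1:
        return types.pop()
    for preferred in (SeqType.AMINO_ACID, SeqType.NUCLEOTIDE, SeqType.STRUCTURE):
        if preferred in types:
            return preferred
    raise InvalidInputError("no alignments given")  # pragma: no cover


def slice_partition(sm: Supermatrix, partition: Partition) -> Alignment:
    """Extract one gene back out of the supermatrix.

    Rows that were padded for this gene (recorded in ``sm.padded``)
    are dropped, so the result reproduces the original gene alignment
    (same taxa, same residues) — the concatenation round-trip.
    """
    padded_taxa = {t for t, g in sm.padded if g == partition.gene_name}
    records = []
    for rec in sm.alignment:
        if rec.name in padded_taxa:
            continue
        piece = rec.residues[partition.start - 1 : partition.end]
        records.append(SequenceRecord(rec.name, piece, partition.seqtype))
    if not records:
        raise ConsistencyError(
            f"partition {partition.gene_name!r} contains only padded rows"
        )
    return Alignment(records, source=partition.gene_name)


def resolve_input_order(paths: Iterable[str | Path]) -> list[Path]:
    """Deterministic input ordering.

    Explicit files keep their given order; a directory argument
    expands to its files in lexicographic name order.  Listing the
    same file twice is an error.
    """
    paths = list(paths)
    if not paths:
        raise InvalidInputError("no input paths given")
    resolved: list[Path] = []
    for p in paths:
        p = Path(p)
        if p.is_dir():
            resolved.extend(sorted(q for q in p.iterdir() if q.is_file()))
        else:
            resolved.append(p)
    seen: set[Path] = set()
    for p in resolved:
        key = p.resolve()
        if key in seen:
            raise ConsistencyError(f"input path given twice: {p}")
        seen.add(key)
    return resolved
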