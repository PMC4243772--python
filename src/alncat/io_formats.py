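"""Alignment readers and writers plus partition and report files.

Readers accept FASTA, CLUSTAL, and relaxed PHYLIP (sequential or
interleaved) with automatic format detection; writers emit FASTA,
relaxed-sequential PHYLIP, and NEXUS.  Parsing of the sequence formats
is delegated to Biopython's ``AlignIO``; the NEXUS writer is local so
that a MrBayes command block with per-partition charsets can be
appended.  Partition files for RAxML and MrBayes and the plain-text
info report are also produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

from Bio import AlignIO

from .core import (
    Alignment,
    AlncatError,
    ConsistencyError,
    InvalidInputError,
    SeqType,
    SequenceRecord,
    validate_alignment,
)

if TYPE_CHECKING:  # pragma: no cover
    from .concatenation import PartitionMap, Supermatrix


class FormatError(AlncatError):
    """A file could not be parsed in its declared or detected format."""


#: canonical lower-case format names
FASTA, PHYLIP, NEXUS, CLUSTAL = "fasta", "phylip", "nexus", "clustal"
READ_FORMATS = (FASTA, CLUSTAL, PHYLIP)
WRITE_FORMATS = (FASTA, PHYLIP, NEXUS)

_EXTENSIONS = {FASTA: ".fas", PHYLIP: ".phy", NEXUS: ".nex"}


@dataclass
class OutputOptions:
    """Which formats to write and whether to add partition metadata."""

    formats: tuple[str, ...] = (FASTA,)
    nexus_mrbayes_block: bool = False
    write_partitions: bool = False

    def __post_init__(self) -> None:
        if not self.formats:
            self.formats = (FASTA,)
        bad = [f for f in self.formats if f not in WRITE_FORMATS]
        if bad:
            raise InvalidInputError(f"unsupported output format(s): {bad}")


def sniff_format(path: str | Path) -> str:
    """Detect the format of an alignment file from its first line.

    ``>`` as the first non-blank character means FASTA; a first line
    containing the word CLUSTAL means CLUSTAL; a leading pair of
    integers (ntax nchar) means PHYLIP.
    """
    with open(path, encoding="utf-8", errors="replace") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                return FASTA
            if stripped.upper().startswith("CLUSTAL"):
                return CLUSTAL
            parts = stripped.split()
            if len(parts) >= 2 and parts[0].isdigit() and parts[1].isdigit():
                return PHYLIP
            break
    raise FormatError(f"{path}: cannot determine alignment format from first line")


def _read_phylip(path: Path) -> list[tuple[str, str]]:
    # Relaxed interleaved covers one-block sequential files with full
    # names (the dialect this package writes); strict dialects are
    # fallbacks for legacy 10-character-name files.
    last_error: Exception | None = None
    for dialect in ("phylip-relaxed", "phylip-sequential", "phylip"):
        try:
            msa = AlignIO.read(str(path), dialect)
            return [(r.id, str(r.seq)) for r in msa]
        except ValueError as exc:
            last_error = exc
    raise FormatError(f"{path}: {last_error}") from last_error


def read_alignment(path: str | Path, format_hint: str | None = None) -> Alignment:
    """Read one aligned sequence file into an :class:`Alignment`.

    Parameters
    ----------
    path
        FASTA, CLUSTAL, or PHYLIP file.
    format_hint
        One of ``fasta``/``clustal``/``phylip``; detected from the
        file content when omitted.

    Raises
    ------
    FormatError
        If the file cannot be parsed.
    ConsistencyError
        If the parsed records are ragged or carry duplicate names.
    """
    path = Path(path)
    if not path.is_file():
        raise InvalidInputError(f"{path}: no such file")
    fmt = (format_hint or sniff_format(path)).lower()
    if fmt not in READ_FORMATS:
        raise InvalidInputError(f"unsupported input format {fmt!r}")
    if fmt == FASTA:
        records = _read_fasta(path)
    elif fmt == PHYLIP:
        records = _read_phylip(path)
    else:
        try:
            msa = AlignIO.read(str(path), CLUSTAL)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        records = [(r.id, str(r.seq)) for r in msa]
    if not records:
        raise FormatError(f"{path}: file contains no sequences")
    try:
        seq_records = _typed_records(records)
    except InvalidInputError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    alignment = Alignment(seq_records, source=path.name)
    violations = validate_alignment(alignment)
    if violations:
        raise ConsistencyError("; ".join(violations))
    return alignment


def _typed_records(records: list[tuple[str, str]]) -> list[SequenceRecord]:
    # one file is one data type: structure strings keep their own
    # type, everything else is typed from the pooled residues of the
    # whole file, so a short protein record that happens to spell only
    # A/C/G/T letters cannot make the file look mixed
    from .core import detect_seqtype

    per_record = [detect_seqtype(seq) for _, seq in records]
    pooled_residues = "".join(
        seq
        for (_, seq), t in zip(records, per_record)
        if t is not SeqType.STRUCTURE
    )
    pooled = detect_seqtype(pooled_residues) if pooled_residues else None
    return [
        SequenceRecord(name, seq, t if t is SeqType.STRUCTURE else pooled)
        for (name, seq), t in zip(records, per_record)
    ]


def _read_fasta(path: Path) -> list[tuple[str, str]]:
    """Permissive FASTA reader: body lines (including blanks between
    them) are concatenated into the current record; CR/LF normalised."""
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name = line[1:].strip()
            if not name:
                raise FormatError(f"{path}: empty sequence name at line {lineno}")
            chunks = []
        elif line:
            if name is None:
                raise FormatError(
                    f"{path}: sequence data before first '>' at line {lineno}"
                )
            chunks.append(line.replace(" ", ""))
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


# ---------------------------------------------------------------------------
# writers


def write_alignment(
    data: "Alignment | Supermatrix",
    options: OutputOptions,
    out_dir: str | Path,
    base_name: str | None = None,
) -> list[Path]:
    """Write an alignment (or a supermatrix) in every selected format.

    Returns the list of files written.  NEXUS output is a ``DATA``
    block with ``MISSING=?`` and ``GAP=-``; when
    ``options.nexus_mrbayes_block`` is set and the data carries a
    partition map, a ``mrbayes`` block with one charset per partition
    is appended.
    """
    from .concatenation import Supermatrix  # local import to avoid a cycle

    partitions = None
    if isinstance(data, Supermatrix):
        alignment = data.alignment
        partitions = data.partitions
    else:
        alignment = data
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = base_name or Path(alignment.source).stem or "alignment"
    written: list[Path] = []
    for fmt in options.formats:
        out = out_dir / f"{stem}{_EXTENSIONS[fmt]}"
        if fmt == FASTA:
            _write_fasta(alignment, out)
        elif fmt == PHYLIP:
            _write_phylip(alignment, out)
        else:
            _write_nexus(
                alignment,
                out,
                partitions if options.nexus_mrbayes_block else None,
            )
        written.append(out)
    return written


def _write_fasta(alignment: Alignment, out: Path) -> None:
    with open(out, "w", encoding="utf-8") as fh:
        for rec in alignment:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


def _write_phylip(alignment: Alignment, out: Path) -> None:
    # relaxed sequential dialect: full names, one sequence per line
    pad = max(len(r.name) for r in alignment) + 2
    with open(out, "w", encoding="utf-8") as fh:
        fh.write(f" {len(alignment)} {alignment.length}\n")
        for rec in alignment:
            fh.write(f"{rec.name:<{pad}}{rec.residues}\n")


_NEXUS_DATATYPE = {
    SeqType.NUCLEOTIDE: "DNA",
    SeqType.AMINO_ACID: "PROTEIN",
    SeqType.STRUCTURE: "STANDARD",
}


def _nexus_datatype(alignment: Alignment, partitions: "PartitionMap | None") -> str:
    if partitions is not None:
        types = {p.seqtype for p in partitions}
        if len(types) > 1:
            spans = ",".join(
                f"{_NEXUS_DATATYPE[p.seqtype]}:{p.start}-{p.end}" for p in partitions
            )
            return f"MIXED({spans})"
    return _NEXUS_DATATYPE[alignment.alignment_seqtype]


def _write_nexus(
    alignment: Alignment, out: Path, partitions: "PartitionMap | None"
) -> None:
    datatype = _nexus_datatype(alignment, partitions)
    with open(out, "w", encoding="utf-8") as fh:
        fh.write("#NEXUS\n\n")
        fh.write("BEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(alignment)} NCHAR={alignment.length};\n")
        fh.write(
            f"  FORMAT DATATYPE={datatype} MISSING=? GAP=- INTERLEAVE=NO;\n"
        )
        fh.write("  MATRIX\n")
        pad = max(len(r.name) for r in alignment) + 2
        for rec in alignment:
            fh.write(f"    {rec.name:<{pad}}{rec.residues}\n")
        fh.write("  ;\nEND;\n")
        if partitions is not None:
            fh.write("\nBEGIN MRBAYES;\n")
            for p in partitions:
                fh.write(f"  charset {p.gene_name} = {p.start}-{p.end};\n")
            names = ", ".join(p.gene_name for p in partitions)
            fh.write(f"  partition combined = {len(partitions)}: {names};\n")
            fh.write("  set partition = combined;\n")
            fh.write("END;\n")


# ---------------------------------------------------------------------------
# partition files


def _check_partitions(pm: "PartitionMap") -> None:
    if not pm:
        raise ConsistencyError("partition map is empty")
    expected_start = 1
    for p in pm:
        if p.start != expected_start or p.end < p.start:
            raise ConsistencyError(
                f"partition {p.gene_name!r} ({p.start}-{p.end}) is not contiguous "
                f"with its predecessor (expected start {expected_start})"
            )
        expected_start = p.end + 1


def write_partitions_raxml(
    pm: "PartitionMap", out: str | Path, protein_model: str = "WAG"
) -> Path:
    """Write a RAxML-style partition file: one ``MODEL, gene = start-end``
    line per partition, 1-based inclusive coordinates.

    Nucleotide partitions are labelled ``DNA``.  Amino-acid partitions
    get *protein_model* as a placeholder label (best-fit model
    selection is outside this package's scope); structure partitions
    are labelled ``MULTI``.
    """
    _check_partitions(pm)
    out = Path(out)
    labels = {
        SeqType.NUCLEOTIDE: "DNA",
        SeqType.AMINO_ACID: protein_model,
        SeqType.STRUCTURE: "MULTI",
    }
    with open(out, "w", encoding="utf-8") as fh:
        for p in pm:
            fh.write(f"{labels[p.seqtype]}, {p.gene_name} = {p.start}-{p.end}\n")
    return out


def write_partitions_mrbayes(pm: "PartitionMap", out: str | Path) -> Path:
    """Write a stand-alone MrBayes block with per-partition charsets."""
    _check_partitions(pm)
    out = Path(out)
    with open(out, "w", encoding="utf-8") as fh:
        fh.write("begin mrbayes;\n")
        for p in pm:
            fh.write(f"  charset {p.gene_name} = {p.start}-{p.end};\n")
        names = ", ".join(p.gene_name for p in pm)
        fh.write(f"  partition combined = {len(pm)}: {names};\n")
        fh.write("  set partition = combined;\n")
        fh.write("end;\n")
    return out


# ---------------------------------------------------------------------------
# info report


_GC_BASES = frozenset("GC")
_NT_DENOM = frozenset("ACGTU")


def composition(alignment: Alignment) -> dict[str, int]:
    """Character counts over all residues of all records."""
    counts: dict[str, int] = {}
    for rec in alignment:
        for c in rec.residues:
            counts[c] = counts.get(c, 0) + 1
    return dict(sorted(counts.items()))


def gc_content(alignment: Alignment) -> float | None:
    """GC fraction = (G+C) / (A+C+G+T+U), ignoring ambiguity codes,
    gaps and ``?``.  None for non-nucleotide data or all-gap input."""
    if alignment.alignment_seqtype is not SeqType.NUCLEOTIDE:
        return None
    counts = composition(alignment)
    denom = sum(n for c, n in counts.items() if c in _NT_DENOM)
    if denom == 0:
        return None
    return sum(n for c, n in counts.items() if c in _GC_BASES) / denom


def _report_alignment(
    fh, title: str, alignment: Alignment, fast: bool, type_label: str | None = None
) -> None:
    fh.write(f"{title}\n")
    fh.write(f"  taxa: {len(alignment)}\n")
    fh.write(f"  length: {alignment.length}\n")
    fh.write(f"  sequence type: {type_label or alignment.alignment_seqtype.value}\n")
    if not fast:
        comp = composition(alignment)
        comp_str = ", ".join(f"{c}:{n}" for c, n in comp.items())
        fh.write(f"  composition: {comp_str}\n")
    gc = gc_content(alignment)
    if gc is not None:
        fh.write(f"  GC content: {gc:.4f}\n")


def write_info_report(
    alignments: Sequence[Alignment],
    supermatrix: "Supermatrix | None",
    out: str | Path,
    fast: bool = False,
) -> Path:
    """Write the plain-text info report.

    Per input file and for the supermatrix (when present): taxon
    count, alignment length, sequence type, character composition, and
    GC content for nucleotide data.  With a supermatrix, each gene's
    coordinate range and the padded (replacement) sequences inserted
    for missing taxa are listed too; ``fast`` skips the composition
    and per-fragment detail to mirror the reduced-information speed
    option.
    """
    if not alignments:
        raise InvalidInputError("info report requires at least one alignment")
    out = Path(out)
    with open(out, "w", encoding="utf-8") as fh:
        fh.write("alncat info report\n==================\n\n")
        for aln in alignments:
            _report_alignment(fh, f"input file: {aln.source}", aln, fast)
            fh.write("\n")
        if supermatrix is not None:
            label = None
            if len({p.seqtype for p in supermatrix.partitions}) > 1:
                label = "mixed"
            _report_alignment(fh, "supermatrix", supermatrix.alignment, fast, label)
            if not fast:
                fh.write("  fragments:\n")
                for p in supermatrix.partitions:
                    fh.write(
                        f"    {p.gene_name}: {p.start}-{p.end} ({p.seqtype.value})\n"
                    )
                fh.write("  inserted replacement strings:\n")
                if supermatrix.padded:
                    for taxon, gene in supermatrix.padded:
                        fh.write(f"    {taxon} in {gene}\n")
                else:
                    fh.write("    none\n")
    return out
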