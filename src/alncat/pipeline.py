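"""Run orchestration: every processing stage in one fixed order.

Stages always execute in the hierarchical order

1. sequence renaming
2. sequence translation (nucleotide -> amino acid or vice versa)
3. consensus generation for predefined sequence blocks
4. RY coding
5. exclusion of third codon positions
6. concatenation into a supermatrix
7. extraction of parsimony-informative sites
8. output of edited sequences and reports

Disabled stages are the identity.  Process chains that contradict the
flow direction (for example RY coding *before* translation to amino
acids) are rejected at configuration validation; such tasks require
two separate runs.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from . import concatenation, consensus, informative_sites, io_formats, recoding
from . import renaming as renaming_mod
from . import structure_report as structure_mod
from . import translation as translation_mod
from .core import Alignment, InvalidInputError, SeqType
from .io_formats import OutputOptions

logger = logging.getLogger("alncat")


class TranslateMode(Enum):
    NT_TO_AA = "nt2aa"
    AA_TO_NT = "aa2nt"


class InformativeScope(Enum):
    NONE = "none"
    PER_FILE = "file"
    SUPERMATRIX = "super"
    BOTH = "both"


@dataclass
class RunConfig:
    """Everything one processing run needs; mirrors the CLI flags."""

    inputs: list[str | Path]
    out_dir: str | Path = "alncat_out"
    rename_file: str | Path | None = None
    translate: TranslateMode | None = None
    consensus_file: str | Path | None = None
    consensus_method: consensus.ConsensusMethod = consensus.ConsensusMethod.MAJORITY_RULE
    ry_mode: recoding.RyMode | None = None
    exclude_third: bool = False
    concatenate: bool = False
    informative: InformativeScope = InformativeScope.NONE
    output: OutputOptions = field(default_factory=OutputOptions)
    fast_mode: bool = False

    def validate(self) -> None:
        """Reject configurations that contradict the processing order.

        Raised before any file is read.
        """
        if not self.inputs:
            raise InvalidInputError("at least one input file is required")
        if self.exclude_third and self.ry_mode is recoding.RyMode.THIRD_POSITIONS:
            raise InvalidInputError(
                "third-position RY coding and third-position exclusion are "
                "mutually exclusive in one run"
            )
        if self.translate is TranslateMode.NT_TO_AA and (
            self.ry_mode is not None or self.exclude_third
        ):
            raise InvalidInputError(
                "RY coding or third-position exclusion cannot precede "
                "nucleotide-to-amino-acid translation; run the tool twice "
                "(recode first, then translate)"
            )
        if self.informative in (
            InformativeScope.SUPERMATRIX,
            InformativeScope.BOTH,
        ) and not self.concatenate:
            raise InvalidInputError(
                "supermatrix informative-site extraction requires concatenation"
            )


@dataclass
class RunSummary:
    """What a run produced: files written, warnings, per-stage counts."""

    outputs: list[Path] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)
    supermatrix: "concatenation.Supermatrix | None" = None
    alignments: list[Alignment] = field(default_factory=list)


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute all enabled stages on the configured inputs."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = RunSummary()

    paths = concatenation.resolve_input_order(config.inputs)
    alignments = [io_formats.read_alignment(p) for p in paths]
    logger.info("read %d input file(s)", len(alignments))
    summary.stage_counts["inputs"] = len(alignments)

    # 1. renaming
    if config.rename_file is not None:
        rename_map = renaming_mod.parse_rename_file(config.rename_file)
        applied = 0
        renamed = []
        report_lines = []
        for aln in alignments:
            aln, report = renaming_mod.apply_renames(aln, rename_map)
            renamed.append(aln)
            applied += len(report.applied)
            report_lines += [
                f"{old}\t{new}\t{src}" for old, new, src in report.applied
            ]
        alignments = renamed
        summary.stage_counts["renamed"] = applied
        rename_out = out_dir / "rename_report.txt"
        rename_out.write_text(
            "old\tnew\tfile\n" + "\n".join(report_lines) + "\n", encoding="utf-8"
        )
        summary.outputs.append(rename_out)
        logger.info("renamed %d sequence(s)", applied)

    # 2. translation (only suitable files are touched)
    if config.translate is TranslateMode.NT_TO_AA:
        translated = []
        for aln in alignments:
            aln, warns = translation_mod.translate_nt_to_aa(aln)
            summary.warnings += warns
            translated.append(aln)
        alignments = translated
        summary.stage_counts["translated"] = len(alignments)
    elif config.translate is TranslateMode.AA_TO_NT:
        alignments = [
            translation_mod.reverse_translate_alignment(a) for a in alignments
        ]
        summary.stage_counts["translated"] = len(alignments)
    for warning in summary.warnings:
        logger.warning("%s", warning)

    # 3. consensus
    if config.consensus_file is not None:
        blocks = consensus.parse_block_file(config.consensus_file)
        alignments = [
            consensus.build_consensus(a, blocks, config.consensus_method)
            for a in alignments
        ]
        summary.stage_counts["consensus_blocks"] = len(blocks)

    # 4. RY coding
    if config.ry_mode is not None:
        alignments = [recoding.ry_encode(a, config.ry_mode) for a in alignments]
        summary.stage_counts["ry_coded"] = sum(
            1 for a in alignments if a.alignment_seqtype is SeqType.NUCLEOTIDE
        )

    # 5. third-position exclusion
    if config.exclude_third:
        alignments = [recoding.exclude_third_positions(a) for a in alignments]

    # 6. concatenation
    supermatrix = None
    if config.concatenate:
        supermatrix = concatenation.concatenate(alignments)
        summary.supermatrix = supermatrix
        summary.stage_counts["supermatrix_taxa"] = len(supermatrix.alignment)
        summary.stage_counts["supermatrix_length"] = supermatrix.length
        logger.info(
            "supermatrix: %d taxa x %d columns, %d partition(s), %d padded cell(s)",
            len(supermatrix.alignment),
            supermatrix.length,
            len(supermatrix.partitions),
            len(supermatrix.padded),
        )

    # 7. parsimony-informative extraction
    informative_outputs: list[tuple[str, Alignment]] = []
    if config.informative in (InformativeScope.PER_FILE, InformativeScope.BOTH):
        for aln in alignments:
            sub, idx = informative_sites.extract_informative(aln)
            summary.stage_counts[f"informative:{aln.source}"] = len(idx)
            if sub is not None:
                informative_outputs.append(
                    (f"{Path(aln.source).stem}_informative", sub)
                )
    if supermatrix is not None and config.informative in (
        InformativeScope.SUPERMATRIX,
        InformativeScope.BOTH,
    ):
        sub, idx = informative_sites.extract_informative(supermatrix.alignment)
        summary.stage_counts["informative:supermatrix"] = len(idx)
        if sub is not None:
            informative_outputs.append(("supermatrix_informative", sub))

    # 8. output
    if supermatrix is not None:
        summary.outputs += io_formats.write_alignment(
            supermatrix, config.output, out_dir, base_name="supermatrix"
        )
        if config.output.write_partitions:
            summary.outputs.append(
                io_formats.write_partitions_raxml(
                    supermatrix.partitions, out_dir / "partitions_raxml.txt"
                )
            )
            summary.outputs.append(
                io_formats.write_partitions_mrbayes(
                    supermatrix.partitions, out_dir / "partitions_mrbayes.nex"
                )
            )
    else:
        for aln in alignments:
            summary.outputs += io_formats.write_alignment(
                aln, config.output, out_dir, base_name=Path(aln.source).stem
            )
    for base, aln in informative_outputs:
        summary.outputs += io_formats.write_alignment(
            aln, config.output, out_dir, base_name=base
        )

    structure_tables = [
        (aln.source, structure_mod.parse_dot_bracket(aln.records[0].residues))
        for aln in alignments
        if aln.alignment_seqtype is SeqType.STRUCTURE
    ]
    if structure_tables:
        summary.outputs.append(
            structure_mod.write_structure_report(
                supermatrix, structure_tables, out_dir / "structure_report.txt"
            )
        )

    summary.outputs.append(
        io_formats.write_info_report(
            alignments, supermatrix, out_dir / "info_report.txt", fast=config.fast_mode
        )
    )
    summary.alignments = alignments
    logger.info("wrote %d output file(s) to %s", len(summary.outputs), out_dir)
    return summary


def configure_logging(verbose: bool = True, log_file: str | Path | None = None) -> None:
    """Send stage logs to stderr and, optionally, a run log file."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file, encoding="utf-8"))
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
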