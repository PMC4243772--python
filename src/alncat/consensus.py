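"""Consensus sequences for named blocks of records.

Three column rules are offered:

``MOST_FREQUENT``
    The plurality state wins.  A tie among plain nucleotide bases is
    resolved to the IUPAC code covering the tied bases; ties
    involving ambiguity codes, and all amino-acid ties, give ``?``.
``MAJORITY_RULE``
    A state must occur in strictly more than 50% of the block's
    sequences (gap-bearing sequences stay in the denominator);
    otherwise ``?``.
``STRICT``
    Nucleotide columns collapse to the IUPAC code covering every base
    present, ignoring ``-`` and ``?`` as long as any base exists;
    amino-acid columns with more than one state give ``X``.  A column
    of only gaps and missing data gives ``?`` under every rule.

Input ambiguity codes are counted as their own states by the two
frequency-based rules and expanded into the union by the strict rule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from .core import (
    Alignment,
    ConsistencyError,
    GAP_CHARS,
    InvalidInputError,
    SeqType,
    SequenceRecord,
)
from .translation import AMBIGUITY_MAP, IUPAC_FROM_SET


class ConsensusMethod(Enum):
    MOST_FREQUENT = "mostfreq"
    MAJORITY_RULE = "majority"
    STRICT = "strict"


@dataclass
class BlockSpec:
    """A named block: the sequence names whose columns are summarised."""

    block_name: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise InvalidInputError(f"block {self.block_name!r} has no members")


def parse_block_file(path: str | Path) -> list[BlockSpec]:
    """Parse a block-definition file.

    One block per non-blank line: ``block_name : member1,member2,...``.
    Block names must be unique and no sequence may belong to two
    blocks.
    """
    path = Path(path)
    blocks: list[BlockSpec] = []
    seen_names: set[str] = set()
    seen_members: set[str] = set()
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if ":" not in line:
            raise InvalidInputError(
                f"{path}:{lineno}: expected 'block_name : member1,member2,...'"
            )
        name, _, members_part = line.partition(":")
        name = name.strip()
        members = [m.strip() for m in members_part.split(",") if m.strip()]
        if not name or not members:
            raise InvalidInputError(f"{path}:{lineno}: empty block name or member list")
        if name in seen_names:
            raise ConsistencyError(f"{path}:{lineno}: duplicate block name {name!r}")
        overlap = seen_members & set(members)
        if overlap:
            raise ConsistencyError(
                f"{path}:{lineno}: sequence(s) {sorted(overlap)} assigned to two blocks"
            )
        seen_names.add(name)
        seen_members.update(members)
        blocks.append(BlockSpec(name, members))
    return blocks


def iupac_union(bases: set[str] | frozenset[str]) -> str:
    """The unique IUPAC code whose expansion equals *bases* (⊆ ACGT)."""
    if not bases:
        raise InvalidInputError("cannot form the IUPAC code of an empty base set")
    key = frozenset(bases)
    code = IUPAC_FROM_SET.get(key)
    if code is None:
        raise InvalidInputError(f"not a set of concrete bases: {sorted(bases)}")
    return code


_PLAIN_BASES = frozenset("ACGTU")


def consensus_column(
    states: list[str], method: ConsensusMethod, seqtype: SeqType
) -> str:
    """Consensus character for one alignment column of a block."""
    if not states:
        raise InvalidInputError("empty column")
    states = [s.upper() for s in states]
    informative = [s for s in states if s not in GAP_CHARS]

    if method is ConsensusMethod.STRICT:
        if not informative:
            return "?"
        if seqtype is SeqType.NUCLEOTIDE:
            union: set[str] = set()
            for s in informative:
                union |= AMBIGUITY_MAP[s]
            return iupac_union(union)
        distinct = set(informative)
        return informative[0] if len(distinct) == 1 else "X"

    if not informative:
        return "?"
    counts = Counter(informative)
    top = max(counts.values())

    if method is ConsensusMethod.MAJORITY_RULE:
        # denominator is the full block size, gaps included; the
        # threshold is strict (exactly 50% is not a majority)
        winners = [s for s, n in counts.items() if n == top]
        if top * 2 > len(states) and len(winners) == 1:
            return winners[0]
        return "?"

    # MOST_FREQUENT
    winners = sorted(s for s, n in counts.items() if n == top)
    if len(winners) == 1:
        return winners[0]
    if seqtype is SeqType.NUCLEOTIDE and all(w in _PLAIN_BASES for w in winners):
        return iupac_union(set().union(*(AMBIGUITY_MAP[w] for w in winners)))
    return "?"


def build_consensus(
    alignment: Alignment, blocks: list[BlockSpec], method: ConsensusMethod
) -> Alignment:
    """Replace each block's records by one consensus record.

    The output holds one consensus record per block (named after the
    block, placed where the block's first member was) plus every
    record not assigned to any block, unchanged.
    """
    by_name = {rec.name: rec for rec in alignment}
    for block in blocks:
        missing = [m for m in block.members if m not in by_name]
        if missing:
            raise ConsistencyError(
                f"{alignment.source}: block {block.block_name!r} member(s) "
                f"{missing} not present in alignment"
            )
    member_to_block = {m: b for b in blocks for m in b.members}
    emitted: set[str] = set()
    out_records: list[SequenceRecord] = []
    for rec in alignment:
        block = member_to_block.get(rec.name)
        if block is None:
            out_records.append(rec)
            continue
        if block.block_name in emitted:
            continue
        emitted.add(block.block_name)
        rows = [by_name[m].residues for m in block.members]
        chars = [
            consensus_column([row[i] for row in rows], method, alignment.alignment_seqtype)
            for i in range(alignment.length)
        ]
        out_records.append(
            SequenceRecord(
                block.block_name, "".join(chars), alignment.alignment_seqtype
            )
        )
    return Alignment(out_records, source=alignment.source)
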