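"""Dot-bracket secondary-structure parsing and the stem/loop report.

A dot-bracket string encodes RNA secondary structure: matched
parentheses are base-paired (stem) positions, dots are unpaired (loop)
positions.  ``-`` and ``?`` are ignored positions — neither stem nor
loop.  Pairs are matched with a stack, so they are properly nested by
construction; pseudoknot alphabets ([], {}, <>) are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .concatenation import Supermatrix
from .core import AlncatError, InvalidInputError


class StructureParseError(AlncatError):
    """Unbalanced or illegal dot-bracket input; carries the 1-based
    position of the offending character."""

    def __init__(self, message: str, position: int):
        super().__init__(message)
        self.position = position


@dataclass
class PairingTable:
    """Stem pairs and loop positions of one structure string (1-based)."""

    pairs: list[tuple[int, int]] = field(default_factory=list)
    loops: list[int] = field(default_factory=list)
    #: ignored '-'/'?' positions with their original character
    ignored: list[tuple[int, str]] = field(default_factory=list)
    length: int = 0

    def to_dot_bracket(self) -> str:
        """Regenerate the dot-bracket string (ignored characters are
        restored verbatim)."""
        chars = ["."] * self.length
        for open_pos, close_pos in self.pairs:
            chars[open_pos - 1] = "("
            chars[close_pos - 1] = ")"
        for pos, c in self.ignored:
            chars[pos - 1] = c
        return "".join(chars)


_PSEUDOKNOT_CHARS = set("[]{}<>")


def parse_dot_bracket(s: str) -> PairingTable:
    """Parse a dot-bracket string into stem pairs and loop positions.

    Each ``)`` pairs with the most recent unmatched ``(``.  Raises
    :class:`StructureParseError` (with the offending 1-based position)
    on an unmatched bracket or an illegal character.
    """
    if not s:
        raise InvalidInputError("empty structure string")
    table = PairingTable(length=len(s))
    stack: list[int] = []
    for pos, c in enumerate(s, 1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise StructureParseError(
                    f"unmatched ')' at position {pos}", position=pos
                )
            table.pairs.append((stack.pop(), pos))
        elif c == ".":
            table.loops.append(pos)
        elif c in "-?":
            table.ignored.append((pos, c))
        elif c in _PSEUDOKNOT_CHARS:
            raise StructureParseError(
                f"pseudoknot bracket {c!r} at position {pos} is not supported "
                "(only '(', ')', '.', '-', '?' are accepted)",
                position=pos,
            )
        else:
            raise StructureParseError(
                f"illegal structure character {c!r} at position {pos}", position=pos
            )
    if stack:
        raise StructureParseError(
            f"unclosed '(' at position {stack[0]}", position=stack[0]
        )
    table.pairs.sort()
    return table


def shift_table(table: PairingTable, offset: int, total_length: int) -> PairingTable:
    """Translate infile coordinates into supermatrix coordinates by
    adding *offset* (= partition start − 1)."""
    return PairingTable(
        pairs=[(a + offset, b + offset) for a, b in table.pairs],
        loops=[p + offset for p in table.loops],
        ignored=[(p + offset, c) for p, c in table.ignored],
        length=total_length,
    )


def _write_table(fh, title: str, table: PairingTable) -> None:
    fh.write(f"{title}\n")
    fh.write(f"  stem pairs ({len(table.pairs)}):\n")
    for a, b in table.pairs:
        fh.write(f"    {a} - {b}\n")
    loops = ", ".join(str(p) for p in table.loops) or "none"
    fh.write(f"  loop positions ({len(table.loops)}): {loops}\n")


def write_structure_report(
    supermatrix: Supermatrix | None,
    per_file: Sequence[tuple[str, PairingTable]],
    out: str | Path,
) -> Path:
    """Write the stem/loop report for all structure inputs.

    One section per source file plus, when a supermatrix exists, one
    section with each table shifted by its gene's partition offset.
    Pad positions inserted for taxa missing a structure gene are dots
    and therefore count as loop positions of the pad.
    """
    if not per_file:
        raise InvalidInputError("no structure strings among the inputs")
    out = Path(out)
    offsets = {}
    total = 0
    if supermatrix is not None:
        total = supermatrix.length
        offsets = {p.gene_name: p.start - 1 for p in supermatrix.partitions}
    with open(out, "w", encoding="utf-8") as fh:
        fh.write("alncat structure report\n=======================\n\n")
        for source, table in per_file:
            _write_table(fh, f"input file: {source}", table)
            fh.write("\n")
        if supermatrix is not None:
            fh.write("supermatrix coordinates\n")
            for source, table in per_file:
                gene = Path(source).stem or source
                if gene not in offsets:
                    continue
                shifted = shift_table(table, offsets[gene], total)
                _write_table(fh, f"  gene {gene}:", shifted)
    return out
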