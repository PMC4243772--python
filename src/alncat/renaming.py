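"""Sequence renaming from a tab-delimited map.

Renaming happens before any other processing so that taxa can be
matched across input files by their final names.  Matching is exact,
case-sensitive, and whole-name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .core import Alignment, ConsistencyError, InvalidInputError


class RenameParseError(InvalidInputError):
    """A rename file line could not be parsed."""


@dataclass
class RenameMap:
    """old name -> new name, parsed from a two-column tab file."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        news = list(self.entries.values())
        if len(set(news)) != len(news):
            raise ConsistencyError("rename map assigns the same new name twice")

    def __len__(self) -> int:
        return len(self.entries)

    def inverse(self) -> "RenameMap":
        return RenameMap({new: old for old, new in self.entries.items()})


@dataclass
class RenameReport:
    """What a rename pass did: applied (old, new, file) triples and map
    entries that matched nothing in the given alignment."""

    applied: list[tuple[str, str, str]] = field(default_factory=list)
    unused: list[str] = field(default_factory=list)


def parse_rename_file(path: str | Path) -> RenameMap:
    """Parse a rename file: one ``old<TAB>new`` pair per non-blank line.

    Raises
    ------
    RenameParseError
        For a line without exactly one tab, with the line number.
    ConsistencyError
        For a duplicated old name.
    """
    path = Path(path)
    entries: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip():
            continue
        if raw.count("\t") != 1:
            raise RenameParseError(
                f"{path}:{lineno}: expected exactly one tab between old and new name"
            )
        old, new = (part.strip() for part in raw.split("\t"))
        if not old or not new:
            raise RenameParseError(f"{path}:{lineno}: empty name")
        if old in entries:
            raise ConsistencyError(f"{path}:{lineno}: duplicate old name {old!r}")
        entries[old] = new
    return RenameMap(entries)


def apply_renames(
    alignment: Alignment, rename_map: RenameMap
) -> tuple[Alignment, RenameReport]:
    """Rename matching records; everything else passes through untouched.

    Residues are never modified.  Raises :class:`ConsistencyError` if a
    rename would collide with an existing (or another renamed) name.
    """
    report = RenameReport()
    new_names: list[str] = []
    for rec in alignment:
        target = rename_map.entries.get(rec.name)
        if target is not None:
            report.applied.append((rec.name, target, alignment.source))
            new_names.append(target)
        else:
            new_names.append(rec.name)
    if len(set(new_names)) != len(new_names):
        dupes = sorted({n for n in new_names if new_names.count(n) > 1})
        raise ConsistencyError(
            f"{alignment.source}: renaming would create duplicate name(s) {dupes}"
        )
    matched = {old for old, _, _ in report.applied}
    report.unused = sorted(set(rename_map.entries) - matched)
    renamed = [
        type(rec)(name, rec.residues, rec.seqtype)
        for rec, name in zip(alignment.records, new_names)
    ]
    return Alignment(renamed, source=alignment.source), report
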