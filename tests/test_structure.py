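import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alncat.concatenation import concatenate
from alncat.core import InvalidInputError
from alncat.fixtures import random_balanced_dot_bracket
from alncat.structure_report import (
    PairingTable,
    StructureParseError,
    parse_dot_bracket,
    shift_table,
    write_structure_report,
)
from conftest import make_alignment


def test_parse_canonical_nesting():
    t = parse_dot_bracket("((..))")
    assert t.pairs == [(1, 6), (2, 5)]
    assert t.loops == [3, 4]


def test_parse_all_loops():
    t = parse_dot_bracket("....")
    assert t.pairs == [] and t.loops == [1, 2, 3, 4]


def test_ignored_positions():
    t = parse_dot_bracket("(-.)?")
    assert t.pairs == [(1, 4)]
    assert t.loops == [3]
    assert t.ignored == [(2, "-"), (5, "?")]


def test_unbalanced_errors_carry_positions():
    with pytest.raises(StructureParseError) as exc:
        parse_dot_bracket("(()")
    assert exc.value.position == 1
    with pytest.raises(StructureParseError) as exc:
        parse_dot_bracket("())")
    assert exc.value.position == 3


def test_pseudoknot_brackets_rejected():
    with pytest.raises(StructureParseError, match="pseudoknot"):
        parse_dot_bracket("([)]")
    with pytest.raises(InvalidInputError):
        parse_dot_bracket("")


def _nesting_ok(pairs):
    for a, b in pairs:
        for c, d in pairs:
            if (a, b) == (c, d):
                continue
            disjoint = b < c or d < a
            nested = (a < c and d < b) or (c < a and b < d)
            if not (disjoint or nested):
                return False
    return True


@settings(derandomize=True, max_examples=300)
@given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(min_value=1, max_value=60))
def test_random_balanced_strings_round_trip(seed, length):
    import random

    s = random_balanced_dot_bracket(random.Random(seed), length)
    table = parse_dot_bracket(s)
    assert table.to_dot_bracket() == s
    assert _nesting_ok(table.pairs)
    positions = (
        [p for pair in table.pairs for p in pair]
        + table.loops
        + [p for p, _ in table.ignored]
    )
    assert sorted(positions) == list(range(1, len(s) + 1))


@settings(derandomize=True, max_examples=100)
@given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(min_value=2, max_value=40))
def test_unbalanced_strings_error(seed, length):
    import random

    rng = random.Random(seed)
    s = random_balanced_dot_bracket(rng, length)
    # break the balance by flipping or inserting one bracket
    if "(" in s and rng.random() < 0.5:
        i = s.index("(")
        broken = s[:i] + "." + s[i + 1 :]
    else:
        broken = s + ")" if rng.random() < 0.5 else "(" + s
    with pytest.raises(StructureParseError):
        parse_dot_bracket(broken)


def test_shift_to_supermatrix_coordinates():
    table = parse_dot_bracket("(....)")
    shifted = shift_table(table, offset=4, total_length=10)
    assert shifted.pairs == [(5, 10)]
    assert shifted.loops == [6, 7, 8, 9]


def test_structure_report_file(tmp_path):
    nt = make_alignment({"a": "ACGT", "b": "ACGA"}, source="nt.fas")
    ss = make_alignment({"a": "(..)", "b": "(..)"}, source="ss.fas")
    sm = concatenate([nt, ss])
    table = parse_dot_bracket("(..)")
    out = write_structure_report(sm, [("ss.fas", table)], tmp_path / "rep.txt")
    text = out.read_text()
    assert "input file: ss.fas" in text
    assert "1 - 4" in text  # infile coordinates
    assert "5 - 8" in text  # shifted by the partition offset of 4
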