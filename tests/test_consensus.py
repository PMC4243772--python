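import random

import pytest

from alncat.consensus import (
    BlockSpec,
    ConsensusMethod,
    build_consensus,
    consensus_column,
    iupac_union,
    parse_block_file,
)
from alncat.core import ConsistencyError, InvalidInputError, SeqType
from alncat.translation import AMBIGUITY_MAP
from conftest import make_alignment

NT = SeqType.NUCLEOTIDE
AA = SeqType.AMINO_ACID


@pytest.mark.parametrize(
    "bases, code",
    [({"A"}, "A"), ({"A", "C"}, "M"), ({"A", "C", "G", "T"}, "N"), ({"C", "G", "T"}, "B")],
)
def test_iupac_union(bases, code):
    assert iupac_union(bases) == code


def test_iupac_union_rejects_empty_set():
    with pytest.raises(InvalidInputError):
        iupac_union(set())


@pytest.mark.parametrize(
    "states, method, seqtype, expected",
    [
        # most frequent: plurality wins; base ties collapse to IUPAC
        (list("AAC"), ConsensusMethod.MOST_FREQUENT, NT, "A"),
        (list("AC"), ConsensusMethod.MOST_FREQUENT, NT, "M"),
        (list("ACGT"), ConsensusMethod.MOST_FREQUENT, NT, "N"),
        (list("RRAA"), ConsensusMethod.MOST_FREQUENT, NT, "?"),  # tie with ambiguity code
        (list("KR"), ConsensusMethod.MOST_FREQUENT, AA, "?"),  # amino-acid tie
        (list("--?"), ConsensusMethod.MOST_FREQUENT, NT, "?"),
        # majority rule: strictly more than half of the block
        (list("AACCG"), ConsensusMethod.MAJORITY_RULE, NT, "?"),  # 40% is no majority
        (list("AAAC"), ConsensusMethod.MAJORITY_RULE, NT, "A"),  # 75%
        (list("AACC"), ConsensusMethod.MAJORITY_RULE, NT, "?"),  # exactly 50%
        (list("AA--"), ConsensusMethod.MAJORITY_RULE, NT, "?"),  # gaps stay in denominator
        (list("AAA-"), ConsensusMethod.MAJORITY_RULE, NT, "A"),
        (list("KKR"), ConsensusMethod.MAJORITY_RULE, AA, "K"),
        # strict: IUPAC union ignoring gaps/missing while a base exists
        (list("AG-"), ConsensusMethod.STRICT, NT, "R"),
        (list("-?-"), ConsensusMethod.STRICT, NT, "?"),
        (list("AAAA"), ConsensusMethod.STRICT, NT, "A"),
        (list("ANC"), ConsensusMethod.STRICT, NT, "N"),  # ambiguity codes expand
        (list("KKR"), ConsensusMethod.STRICT, AA, "X"),
        (list("KK-"), ConsensusMethod.STRICT, AA, "K"),
    ],
)
def test_consensus_column(states, method, seqtype, expected):
    assert consensus_column(states, method, seqtype) == expected


@pytest.mark.parametrize("method", list(ConsensusMethod))
def test_single_sequence_block_is_identity(method, rng):
    seq = "".join(rng.choice("ACGT-") for _ in range(50)).replace("-", "A", 1)
    aln = make_alignment({"s1": seq, "other": "C" * 50})
    out = build_consensus(aln, [BlockSpec("b1", ["s1"])], method)
    consensus_rec = out.get("b1")
    expected = "".join("?" if c == "-" else c for c in seq)
    # a lone gap column has no state: every method reports '?'
    assert consensus_rec.residues == expected


def test_strict_consensus_expansion_is_superset_of_observed(rng):
    for _ in range(200):
        states = [rng.choice("ACGTRYSWKMN-?") for _ in range(rng.randint(2, 8))]
        out = consensus_column(states, ConsensusMethod.STRICT, NT)
        observed = set()
        for s in states:
            if s not in "-?":
                observed |= AMBIGUITY_MAP[s]
        if not observed:
            assert out == "?"
        else:
            assert AMBIGUITY_MAP[out] >= observed


def test_column_independence_of_row_order(rng):
    for method in ConsensusMethod:
        states = [rng.choice("ACGT-?") for _ in range(6)]
        shuffled = states[:]
        rng.shuffle(shuffled)
        assert consensus_column(states, method, NT) == consensus_column(
            shuffled, method, NT
        )


def test_build_consensus_structure():
    aln = make_alignment({"s1": "AC", "s2": "AG", "s3": "TT"})
    out = build_consensus(aln, [BlockSpec("b", ["s1", "s2"])], ConsensusMethod.STRICT)
    assert out.names == ["b", "s3"]
    assert out.get("b").residues == "AS"
    assert out.get("s3").residues == "TT"  # passthrough untouched


def test_build_consensus_missing_member_errors():
    aln = make_alignment({"s1": "AC"})
    with pytest.raises(ConsistencyError, match="ghost"):
        build_consensus(aln, [BlockSpec("b", ["s1", "ghost"])], ConsensusMethod.STRICT)


def test_parse_block_file(tmp_path):
    path = tmp_path / "blocks.txt"
    path.write_text("popA : s1, s2\npopB : s3,s4\n\n")
    blocks = parse_block_file(path)
    assert [(b.block_name, b.members) for b in blocks] == [
        ("popA", ["s1", "s2"]),
        ("popB", ["s3", "s4"]),
    ]
    (tmp_path / "dup.txt").write_text("a : s1\nb : s1\n")
    with pytest.raises(ConsistencyError):
        parse_block_file(tmp_path / "dup.txt")
    (tmp_path / "bad.txt").write_text("no separator line\n")
    with pytest.raises(InvalidInputError):
        parse_block_file(tmp_path / "bad.txt")
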