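"""Stockholm parsing, writing and structure-string pair extraction."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from rleader.stockholm import (
    NoConsensusStructureError,
    StockholmParseError,
    StructuredAlignment,
    StructureError,
    extract_pairs,
    read_stockholm,
    write_stockholm,
)

SIMPLE = """\
# STOCKHOLM 1.0
seq1 GGAACC
seq2 GGUACC
#=GC SS_cons <<..>>
//
"""

INTERLEAVED = """\
# STOCKHOLM 1.0
seq1 GGA
seq2 GGU
#=GC SS_cons <<.
seq1 ACC
seq2 ACC
#=GC SS_cons .>>
//
"""


class TestReadStockholm:
    def test_single_block(self):
        alns = read_stockholm(SIMPLE)
        assert len(alns) == 1
        aln = alns[0]
        assert len(aln) == 2
        assert aln.consensus_structure == "<<..>>"
        assert aln.records[0] == ("seq1", "GGAACC")

    def test_interleaved_blocks_equal_single_block(self):
        assert read_stockholm(INTERLEAVED) == read_stockholm(SIMPLE)

    def test_multiple_alignments_per_file(self):
        alns = read_stockholm(SIMPLE + SIMPLE)
        assert len(alns) == 2
        assert alns[0] == alns[1]

    def test_ragged_sequence_names_offender(self):
        text = SIMPLE.replace("GGUACC", "GGUAC")
        with pytest.raises(StockholmParseError, match="seq2"):
            read_stockholm(text)

    def test_missing_consensus_structure(self):
        text = "# STOCKHOLM 1.0\nseq1 GGAACC\n//\n"
        with pytest.raises(NoConsensusStructureError):
            read_stockholm(text)

    def test_unknown_annotations_preserved(self):
        text = (
            "# STOCKHOLM 1.0\n"
            "#=GF ID demo\n"
            "#=GF CUSTOM some free metadata\n"
            "#=GS seq1 DE a description\n"
            "seq1 GGAACC\n"
            "#=GC RF xxxxxx\n"
            "#=GC SS_cons <<..>>\n"
            "//\n"
        )
        aln = read_stockholm(text)[0]
        assert aln.metadata["CUSTOM"] == "some free metadata"
        assert aln.column_annotations["RF"] == "xxxxxx"
        assert aln.sequence_annotations == ["#=GS seq1 DE a description"]
        assert read_stockholm(write_stockholm(aln)) == [aln]


class TestWriteStockholm:
    def test_roundtrip_fixture(self):
        alns = read_stockholm(SIMPLE)
        assert read_stockholm(write_stockholm(alns)) == alns

    def test_empty_list_is_header_only(self):
        text = write_stockholm([])
        assert text.startswith("# STOCKHOLM 1.0")
        assert "//" not in text
        assert read_stockholm(text) == []

    def test_thymine_preserved_verbatim(self):
        aln = StructuredAlignment(
            records=[("s1", "GGTACC")], consensus_structure="<<..>>"
        )
        assert "GGTACC" in write_stockholm(aln)
        assert read_stockholm(write_stockholm(aln))[0].records[0][1] == "GGTACC"


class TestExtractPairs:
    @pytest.mark.parametrize(
        "structure, pairs, n_unpaired",
        [
            ("<<...>>", {(0, 6), (1, 5)}, 3),
            ("::::", set(), 4),
            ("<[.>]", {(0, 3), (1, 4)}, 1),
            ("..AA..aa..", {(2, 7), (3, 6)}, 6),
            ("((..))<<>>", {(0, 5), (1, 4), (6, 9), (7, 8)}, 2),
        ],
    )
    def test_examples(self, structure, pairs, n_unpaired):
        table = extract_pairs(structure)
        assert set(table.pairs) == pairs
        assert len(table.unpaired) == n_unpaired

    @pytest.mark.parametrize("bad", ["<<.>", ">", "[..", "Aa)a"])
    def test_unbalanced_raises_with_position(self, bad):
        with pytest.raises(StructureError, match="column"):
            extract_pairs(bad)

    def test_each_column_in_at_most_one_pair(self):
        table = extract_pairs("<<<<....>>>>..<<..>>")
        cols = [c for ij in table.pairs for c in ij]
        assert len(cols) == len(set(cols))


def _oracle_pairs(structure: str) -> set[tuple[int, int]]:
    """Independent stack-based matcher, one explicit stack per class."""
    classes = {"<": ">", "(": ")", "[": "]", "{": "}"}
    classes.update({c: c.lower() for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"})
    closers = {v: k for k, v in classes.items()}
    stacks: dict[str, list[int]] = {k: [] for k in classes}
    out = set()
    for i, c in enumerate(structure):
        if c in classes:
            stacks[c].append(i)
        elif c in closers:
            out.add((stacks[closers[c]].pop(), i))
    return out


@st.composite
def balanced_structure(draw):
    """Random balanced structure string (possibly with pseudoknot class)."""
    depth_units = draw(
        st.lists(
            st.sampled_from(["<>", "()", "[]", "Aa", "Bb"]), min_size=0, max_size=40
        )
    )
    fillers = draw(st.lists(st.sampled_from(".:_,-"), min_size=1, max_size=20))
    s = ""
    for open_close in depth_units:
        s = open_close[0] + s + open_close[1]
    return s + "".join(fillers)


@given(balanced_structure())
@settings(max_examples=150, deadline=None)
def test_extract_pairs_matches_stack_oracle(structure):
    assert set(extract_pairs(structure).pairs) == _oracle_pairs(structure)


@st.composite
def random_alignment(draw):
    n = draw(st.integers(min_value=1, max_value=6))
    length = draw(st.integers(min_value=1, max_value=30))
    seqs = [
        draw(
            st.text(alphabet="ACGUT-.acgu", min_size=length, max_size=length)
        )
        for _ in range(n)
    ]
    structure = draw(st.text(alphabet=".:-_", min_size=length, max_size=length))
    return StructuredAlignment(
        records=[(f"s{i}", seq) for i, seq in enumerate(seqs)],
        consensus_structure=structure,
    )


@given(random_alignment())
@settings(max_examples=100, deadline=None)
def test_roundtrip_identity_random_alignments(aln):
    assert read_stockholm(write_stockholm(aln)) == [aln]


def test_cross_check_against_biopython():
    """Our writer's output parses identically under Bio.AlignIO."""
    Bio_AlignIO = pytest.importorskip("Bio.AlignIO")
    aln = read_stockholm(SIMPLE)[0]
    handle = io.StringIO(write_stockholm(aln))
    bio = Bio_AlignIO.read(handle, "stockholm")
    assert [str(r.seq) for r in bio] == [s for _, s in aln.records]
    assert bio.column_annotations["secondary_structure"] == aln.consensus_structure
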