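"""Format readers/writers: Stockholm, FASTA dialects, WUSS, NHX, TSV, pass-throughs."""

import io
import random

import pytest
from Bio import AlignIO

from conftest import random_alignment, random_wuss
from rfamkit.errors import (
    MalformedNewickError,
    MalformedStockholmError,
    NotACovarianceModelError,
    NotAnSvgError,
    RaggedAlignmentError,
    UnbalancedStructureError,
)
from rfamkit.formats import (
    AlignmentFormat,
    parse_consensus_file,
    parse_nhx,
    parse_pdb_tsv,
    parse_regions_tsv,
    parse_stockholm,
    pairing_map,
    passthrough_cm,
    passthrough_svg,
    write_alignment,
    write_consensus_file,
    write_pdb_tsv,
    write_regions_tsv,
    wuss_to_dotbracket,
)
from rfamkit.model import ConsensusStructure, PdbCorrespondence, SeedAlignment, SequenceRegion

MINIMAL = """# STOCKHOLM 1.0
#=GF ID test
seq1 ACGU-ACGU
seq2 AC--UACGU
#=GC SS_cons <<<....>>
//
"""


# ---------------------------------------------------------------------------
# Stockholm
# ---------------------------------------------------------------------------


def test_parse_minimal_stockholm():
    aln = parse_stockholm(MINIMAL)
    assert aln.rows == [("seq1", "ACGU-ACGU"), ("seq2", "AC--UACGU")]
    assert aln.column_annotations["SS_cons"] == "<<<....>>"
    assert aln.file_annotations["ID"] == ["test"]
    assert len(aln.column_annotations["SS_cons"]) == aln.width


def test_missing_header_and_ragged_rows_rejected():
    with pytest.raises(MalformedStockholmError):
        parse_stockholm("seq1 ACGU\n//\n")
    with pytest.raises(RaggedAlignmentError):
        parse_stockholm("# STOCKHOLM 1.0\nseq1 ACGU\nseq2 AC\n//\n")


def test_interleaved_blocks_concatenate_to_single_block_equivalent():
    single = "# STOCKHOLM 1.0\nseq1 ACGUACGU\nseq2 UGCAUGCA\n#=GC SS_cons <<<<>>>>\n//\n"
    interleaved = (
        "# STOCKHOLM 1.0\n"
        "seq1 ACGU\nseq2 UGCA\n#=GC SS_cons <<<<\n"
        "\n"
        "seq1 ACGU\nseq2 UGCA\n#=GC SS_cons >>>>\n"
        "//\n"
    )
    assert parse_stockholm(interleaved) == parse_stockholm(single)


def test_stockholm_round_trip_random_alignments():
    rng = random.Random(1_234)
    for _ in range(50):
        aln = random_alignment(rng)
        assert parse_stockholm(write_alignment(aln, AlignmentFormat.STOCKHOLM)) == aln


def test_stockholm_agrees_with_biopython_on_sequences(case_client):
    """Independent cross-check: Biopython reads the same rows we do."""
    aln = case_client.seed_alignment("RF03120")
    text = write_alignment(aln, AlignmentFormat.STOCKHOLM)
    bio = AlignIO.read(io.StringIO(text), "stockholm")
    assert [(r.id, str(r.seq)) for r in bio] == aln.rows


@pytest.mark.parametrize(
    "fmt, row",
    [(AlignmentFormat.FASTA, "AC-GU."), (AlignmentFormat.FASTAU, "ACGU")],
)
def test_fasta_dialects_gap_handling(fmt, row):
    aln = SeedAlignment(rows=[("r1", "AC-GU.")])
    assert write_alignment(aln, fmt) == f">r1\n{row}\n"


def test_fastau_equals_fasta_with_gaps_deleted():
    rng = random.Random(9)
    for _ in range(20):
        aln = random_alignment(rng)
        fasta = write_alignment(aln, AlignmentFormat.FASTA).splitlines()
        fastau = write_alignment(aln, AlignmentFormat.FASTAU).splitlines()
        for fa, fu in zip(fasta, fastau):
            if fa.startswith(">"):
                assert fa == fu
            else:
                assert fu == fa.replace("-", "").replace(".", "")


def test_pfam_dialect_is_single_block_with_dotbracket_structure():
    aln = SeedAlignment(
        rows=[("r1", "ACGUACGU")],
        column_annotations={"SS_cons": "<<<__>>>"},
    )
    text = write_alignment(aln, AlignmentFormat.PFAM)
    parsed = parse_stockholm(text)
    assert parsed.rows == aln.rows
    assert parsed.column_annotations["SS_cons"] == "<<<..>>>"


# ---------------------------------------------------------------------------
# WUSS / dot-bracket
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "wuss, db",
    [
        ("<<<__>>>", "<<<..>>>"),
        ("::::", "...."),
        (":,_-~.", "......"),
        ("<<((..))>>AA..aa", "<<((..))>>AA..aa"),  # families and pseudoknots kept
    ],
)
def test_wuss_to_dotbracket_examples(wuss, db):
    assert wuss_to_dotbracket(wuss) == db


def test_wuss_unbalanced_rejected():
    with pytest.raises(UnbalancedStructureError):
        wuss_to_dotbracket("<<(>>")
    with pytest.raises(UnbalancedStructureError) as exc:
        wuss_to_dotbracket("..))")
    assert exc.value.position == 3


def oracle_pairing(structure):
    """Independent bracket-matching: one explicit stack per family."""
    pairs = {}
    for o, c in [("<", ">"), ("(", ")"), ("[", "]"), ("{", "}")] + [
        (chr(u), chr(u + 32)) for u in range(ord("A"), ord("Z") + 1)
    ]:
        stack = []
        for pos, ch in enumerate(structure, start=1):
            if ch == o:
                stack.append(pos)
            elif ch == c:
                i = stack.pop()
                pairs[i] = pos
                pairs[pos] = i
    return pairs


def test_wuss_conversion_preserves_pairing_map_on_random_structures():
    rng = random.Random(55)
    for _ in range(200):
        wuss = random_wuss(rng)
        db = wuss_to_dotbracket(wuss)
        assert len(db) == len(wuss)
        assert oracle_pairing(db) == oracle_pairing(wuss) == pairing_map(wuss)
        assert all(ch == "." or ch in "<>()[]{}" or ch.isalpha() for ch in db)


# ---------------------------------------------------------------------------
# Consensus-structure files
# ---------------------------------------------------------------------------


def test_consensus_file_round_trip():
    cs = ConsensusStructure(sequence="ACGU", structure="<..>")
    text = write_consensus_file(cs)
    assert text == "ACGU\n<..>\n"
    assert parse_consensus_file(text) == cs


def test_case_study_consensus_lengths_equal(case_client):
    for notation in ("DB", "WUSS"):
        cs = case_client.consensus_structure("RF03120", notation)
        assert len(cs.sequence) == len(cs.structure)
    db = case_client.consensus_structure("RF03120", "DB")
    assert not (set(db.structure) & set(":,_~-"))  # fully converted to dot-bracket


# ---------------------------------------------------------------------------
# NHX trees
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "newick, tips, internal",
    [
        ("(A,B,(C,D));", 4, 2),
        ("A;", 1, 0),
        ("((A:1,B:2):0.5,(C:1,D:1):0.5);", 4, 3),
    ],
)
def test_parse_nhx_counts(newick, tips, internal):
    summary = parse_nhx(newick)
    assert (summary.tip_count, summary.internal_node_count) == (tips, internal)
    assert summary.tip_count == len(summary.tip_labels)


def test_parse_nhx_preserves_comments_and_branch_lengths():
    summary = parse_nhx("((A:0.1,B:0.2)0.9:0.3[&&NHX:S=Eukaryota],C:0.4);")
    assert summary.has_branch_lengths
    assert any("NHX" in c for c in summary.nhx_comments)


def test_malformed_newick_rejected():
    with pytest.raises(MalformedNewickError):
        parse_nhx("(A,B")
    with pytest.raises(MalformedNewickError):
        parse_nhx("(A,(B);")


def test_random_bifurcating_rooted_trees_have_n_minus_1_internals():
    rng = random.Random(31)

    def newick(tips):
        if len(tips) == 1:
            return tips[0]
        k = rng.randint(1, len(tips) - 1)
        return f"({newick(tips[:k])},{newick(tips[k:])})"

    for _ in range(30):
        n = rng.randint(2, 40)
        labels = [f"t{i}" for i in range(n)]
        summary = parse_nhx(newick(labels) + ";")
        assert summary.tip_count == n
        assert summary.internal_node_count == n - 1
        assert sorted(summary.tip_labels) == sorted(labels)


def test_case_study_tree_shape(case_client):
    summary = parse_nhx(case_client.seed_tree("RF03120"))
    assert summary.tip_count == 19
    assert summary.internal_node_count == 17
    assert summary.has_branch_lengths


# ---------------------------------------------------------------------------
# TSV exports
# ---------------------------------------------------------------------------


def test_regions_tsv_round_trip_with_embedded_tabs():
    regions = [
        SequenceRegion("AB1234.1", 5, 100, "desc with\ttab", "Homo\nsapiens"),
    ]
    text = write_regions_tsv(regions)
    assert len(text.strip().split("\n")) == 2
    assert text.strip().split("\n")[1].count("\t") == 4  # no raw embedded tabs
    assert parse_regions_tsv(text) == regions
    assert write_regions_tsv([]).strip().split("\n") == [text.split("\n")[0]]


def test_pdb_tsv_round_trip():
    rows = [PdbCorrespondence("1EHZ", "A", 1, 76, 1, 71)]
    text = write_pdb_tsv(rows)
    assert parse_pdb_tsv(text) == rows


# ---------------------------------------------------------------------------
# Opaque pass-throughs
# ---------------------------------------------------------------------------


def test_cm_passthrough_validates_and_preserves_bytes():
    payload = b"INFERNAL1/a [1.1.4]\nNAME x\n//\n"
    assert passthrough_cm(payload) == payload
    with pytest.raises(NotACovarianceModelError):
        passthrough_cm(b"HMMER3/f\n")


def test_svg_passthrough_validates_and_preserves_bytes():
    payload = b'<?xml version="1.0"?><svg xmlns="x"><g/></svg>'
    assert passthrough_svg(payload) == payload
    with pytest.raises(NotAnSvgError):
        passthrough_svg(b"<html></html>")
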