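"""Sequence/tree data model: I/O round-trips, translation, global identity."""

import pytest
from hypothesis import given, settings, strategies as st

from c4recruit.seq_core import (Alignment, FormatError, OrthologSet, SeqRecord,
                                global_identity, needleman_wunsch, read_fasta,
                                read_newick_string, translate_cds, write_fasta,
                                write_newick_string)

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# FASTA

def test_header_tokens_parsed(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">a|Frob|C3\nMKV\n")
    (rec,) = read_fasta(p, "protein")
    assert (rec.id, rec.species, rec.ptype, rec.residues) == \
        ("a", "Frob", "C3", "MKV")


def test_duplicate_ids_rejected(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">x\nATG\n>x\nATG\n")
    with pytest.raises(FormatError, match="duplicate"):
        read_fasta(p, "dna")


def test_empty_file_and_illegal_characters(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    with pytest.raises(FormatError):
        read_fasta(p, "dna")
    p2 = tmp_path / "bad.fasta"
    p2.write_text(">x\nATGJ\n")
    with pytest.raises(FormatError, match="position 4"):
        read_fasta(p2, "dna")


def test_terminal_stop_stripped_with_warning(tmp_path):
    p = tmp_path / "s.fasta"
    p.write_text(">x\nMKV*\n")
    with pytest.warns(UserWarning, match="terminal"):
        (rec,) = read_fasta(p, "protein")
    assert rec.residues == "MKV"


def test_dot_gap_dialect_rejected():
    with pytest.raises(FormatError, match="'.'"):
        SeqRecord(id="x", residues="MK.V", molecule="protein")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(
    st.tuples(st.text(alphabet="abcXYZ09", min_size=1, max_size=8),
              st.text(alphabet=AA, min_size=1, max_size=90)),
    min_size=1, max_size=6, unique_by=lambda t: t[0]))
def test_fasta_round_trip(tmp_path_factory, entries):
    """write(read(f)) preserves ids, species, ptype and residues."""
    tmp = tmp_path_factory.mktemp("fa")
    records = [SeqRecord(id=rid, residues=seq, molecule="protein")
               for rid, seq in entries]
    path = tmp / "x.fasta"
    write_fasta(records, path)
    back = read_fasta(path, "protein")
    assert [(r.id, r.species, r.ptype, r.residues) for r in back] == \
        [(r.id, r.species, r.ptype, r.residues) for r in records]


# ---------------------------------------------------------------------------
# translation

@pytest.mark.parametrize("cds,protein", [
    ("ATGGCGGCG", "MAA"),
    ("ATGTAA", "M"),  # terminal stop stripped
    ("atggtt", "MV"),  # case-normalized upstream by read_fasta; Seq handles
])
def test_translate_examples(cds, protein):
    rec = SeqRecord(id="x", residues=cds.upper(), molecule="dna")
    assert translate_cds(rec).residues == protein


def test_translate_errors():
    with pytest.raises(FormatError, match="divisible"):
        translate_cds(SeqRecord(id="x", residues="ATGA", molecule="dna"))
    with pytest.raises(FormatError, match="internal stop"):
        translate_cds(SeqRecord(id="x", residues="ATGTAAGCG", molecule="dna"))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.text(alphabet=AA, min_size=1, max_size=50))
def test_translate_backmap_identity(protein):
    """Codon backmap then translation is the identity on proteins."""
    from c4recruit.synthetic_data import backmap_cds
    rec = SeqRecord(id="x", residues=backmap_cds(protein), molecule="dna")
    assert translate_cds(rec).residues == protein


# ---------------------------------------------------------------------------
# global identity

def _all_alignments(a, b):
    """Every global alignment of a and b, as (row_a, row_b) pairs."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ra, rb in _all_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in _all_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)
    if a and b:
        for ra, rb in _all_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)


def _score(ra, rb, match=1.0, mismatch=0.0, gap=-1.0):
    s = 0.0
    for x, y in zip(ra, rb):
        s += gap if "-" in (x, y) else (match if x == y else mismatch)
    return s


@pytest.mark.parametrize("a,b", [
    ("ACGTAC", "ACTTAC"),
    ("AAAA", "TTTT"),
    ("GATTAC", "GCA"),
    ("ACACAC", "CACACA"),
    ("TTGACA", "TTGACA"),
])
def test_nw_score_matches_exhaustive_enumeration(a, b):
    """NW optimum equals brute-force enumeration over all global alignments."""
    ra, rb, score = needleman_wunsch(a, b)
    best = max(_score(x, y) for x, y in _all_alignments(a, b))
    assert score == best
    assert _score(ra, rb) == best
    # identity of the returned alignment is achievable by some optimum
    opt_idents = {
        100.0 * sum(1 for p, q in zip(x, y) if p == q and p != "-") / len(x)
        for x, y in _all_alignments(a, b) if _score(x, y) == best}
    assert global_identity(a, b) in opt_idents


def test_nw_score_agrees_with_biopython_aligner(rng):
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score, aligner.mismatch_score = 1.0, 0.0
    aligner.open_gap_score = aligner.extend_gap_score = -1.0
    for _ in range(20):
        a = "".join(rng.choice(list("ACGT"), size=rng.integers(3, 30)))
        b = "".join(rng.choice(list("ACGT"), size=rng.integers(3, 30)))
        assert needleman_wunsch(a, b)[2] == pytest.approx(aligner.score(a, b))


def test_identity_trivial_cases():
    assert global_identity("ACGT", "ACGT") == 100.0
    assert global_identity("AAAA", "TTTT") == 0.0
    with pytest.raises(ValueError, match="mixed"):
        global_identity(SeqRecord(id="p", residues="MKV", molecule="protein"),
                        SeqRecord(id="d", residues="ATG", molecule="dna"))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=40),
       st.text(alphabet="ACGT", min_size=1, max_size=40))
def test_identity_symmetric_and_100_iff_identical(a, b):
    assert global_identity(a, b) == pytest.approx(global_identity(b, a))
    if a == b:
        assert global_identity(a, b) == 100.0
    else:
        assert global_identity(a, b) < 100.0 or len(a) != len(b)


# ---------------------------------------------------------------------------
# Newick

def test_newick_parse_basics():
    tree = read_newick_string("((A:1,B:1)N1:1,C:2);")
    assert tree.tip_names == {"A", "B", "C"}
    assert tree.node("N1").length == 1.0
    assert tree.tips_under("N1") == {"A", "B"}


def test_newick_errors():
    with pytest.raises(FormatError):
        read_newick_string("((A:1,B:1;")
    with pytest.raises(FormatError, match="duplicate"):
        read_newick_string("(A:1,A:1);")


def test_newick_round_trip(rng):
    """Random labeled trees survive write -> read."""
    counter = [0]

    def random_newick(tips):
        if len(tips) == 1:
            return f"{tips[0]}:{rng.integers(1, 9)}"
        k = int(rng.integers(1, len(tips)))
        left, right = random_newick(tips[:k]), random_newick(tips[k:])
        counter[0] += 1
        return f"({left},{right})I{counter[0]}:{rng.integers(1, 9)}"

    for n in (3, 5, 8):
        tips = [f"t{i}" for i in range(n)]
        text = f"({random_newick(tips[:1])},{random_newick(tips[1:])})R;"
        t1 = read_newick_string(text)
        t2 = read_newick_string(write_newick_string(t1))
        assert t1.tip_names == t2.tip_names
        for node in t1.postorder():
            other = t2.node(node.id)
            assert other.length == pytest.approx(node.length)
            assert {c.id for c in other.children} == \
                {c.id for c in node.children}


def test_ortholog_set_pairing_error():
    tree = read_newick_string("(A:1,C:1);")
    aln = Alignment(records=(
        SeqRecord(id="A", residues="MKV", molecule="protein"),
        SeqRecord(id="B", residues="MKV", molecule="protein")))
    with pytest.raises(ValueError, match="not in tree"):
        OrthologSet(protein_alignment=aln, cds={}, tree=tree)


def test_ortholog_set_translation_mismatch():
    tree = read_newick_string("(A:1,B:1);")
    aln = Alignment(records=(
        SeqRecord(id="A", residues="MKV", molecule="protein"),
        SeqRecord(id="B", residues="MKV", molecule="protein")))
    cds = {"A": SeqRecord(id="A", residues="ATGAAAGCG", molecule="dna")}  # MKA
    with pytest.raises(ValueError, match="disagrees"):
        OrthologSet(protein_alignment=aln, cds=cds, tree=tree)
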