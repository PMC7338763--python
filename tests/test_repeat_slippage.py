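"""Tandem-insertion detection, ancestral element, flanks, Nussinov folding."""

import numpy as np
import pytest

from c4recruit import fixtures as fx
from c4recruit.repeat_slippage import (RepeatInsertion, SlippageEvidence,
                                       _consensus, detect_tandem_insertion,
                                       find_flanking_direct_repeats,
                                       infer_ancestral_unit, nussinov_hairpin,
                                       segment_cds, slippage_report)
from c4recruit.seq_core import Alignment, SeqRecord
from c4recruit.synthetic_data import InsertionSpec, SimConfig, simulate_ortholog_set


def _aln_with_insertion(inserted: dict[str, str], flank_a="MKTE", flank_b="WYHC"):
    """Two non-carriers + carriers with the given inserted segments."""
    span = max(len(s) for s in inserted.values())
    rows = {"bg1": flank_a + "-" * span + flank_b,
            "bg2": flank_a + "-" * span + flank_b}
    for sp, seg in inserted.items():
        rows[sp] = flank_a + seg + "-" * (span - len(seg)) + flank_b
    return Alignment(records=tuple(
        SeqRecord(id=sp, residues=seq, molecule="protein", species=sp)
        for sp, seq in rows.items()))


# ---------------------------------------------------------------------------
# detection against a brute-force oracle

def _oracle_decompose(seq, min_unit=3, max_unit=50, max_mismatch=2):
    """Exhaustive (unit, offset, copies) search, written independently."""
    best = None  # (cover, unit, offset, copies)
    for u in range(min_unit, min(max_unit, len(seq) // 2) + 1):
        for k in range(len(seq) // u, 1, -1):
            for off in range(len(seq) - k * u + 1):
                copies = [seq[off + i * u: off + (i + 1) * u] for i in range(k)]
                cons = _consensus(copies)
                if any(sum(a != b for a, b in zip(c, cons)) > max_mismatch
                       for c in copies):
                    continue
                cand = (k * u, -u, -off, k)
                if best is None or cand > best:
                    best = cand
                break
            if best is not None and -best[1] == u:
                break
    if best is None:
        return None
    return (-best[1], best[3])  # (unit, copies)


@pytest.mark.parametrize("seed", range(12))
def test_planted_tandem_recovered_matches_oracle(seed):
    rng = np.random.default_rng(seed)
    L = int(rng.integers(3, 21))
    k = int(rng.integers(2, 7))
    unit = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=L))
    seg = unit * k
    aln = _aln_with_insertion({"car1": seg})
    (ins,) = detect_tandem_insertion(aln)
    expected = _oracle_decompose(seg)
    assert (ins.unit_length_aa, ins.copies["car1"]) == expected
    assert ins.total_span_aa["car1"] == expected[0] * expected[1]


def test_short_span_reported_as_non_repetitive():
    aln = _aln_with_insertion({"car1": "DEKA"})
    (ins,) = detect_tandem_insertion(aln, min_unit=3)
    assert not ins.repetitive
    assert ins.copies["car1"] == 1


def test_reconstruction_unit_copies_span_variants():
    oset = fx.insertion_ortholog_set()
    (ins,) = detect_tandem_insertion(oset)
    assert ins.unit_length_aa == 13
    assert ins.consensus_unit == fx.UNIT_CONSENSUS
    assert ins.copies == {"Fpal": 4, "Fbid": 4, "Ftri": 4, "Faus": 4,
                          "Fvag": 5, "Fkoc": 5}
    assert ins.total_span_aa["Fbid"] == 52
    assert len(ins.variant_sites) == 4
    assert [pos for pos, _ in ins.variant_sites] == [3, 8, 10, 13]


def test_pairwise_carrier_vs_c3():
    aln = fx.insertion_pairwise_alignment("Ftri", "Fcro")
    (ins,) = detect_tandem_insertion(aln)
    assert (ins.unit_length_aa, ins.copies["Ftri"]) == (13, 4)


def test_deleting_insertion_reproduces_noncarrier_sequence():
    """The carrier minus the inserted span equals the C3 ortholog exactly."""
    oset = fx.insertion_ortholog_set()
    (ins,) = detect_tandem_insertion(oset)
    lo, hi = ins.insertion_column_span
    carrier = oset.protein_alignment.by_species("Fbid").residues
    noncarrier = oset.protein_alignment.by_species("Fcro").residues
    deleted = (carrier[:lo - 1] + carrier[hi:]).replace("-", "")
    assert deleted == noncarrier.replace("-", "")


# ---------------------------------------------------------------------------
# ancestral element

def test_ancestral_element_len_12_minus_one_alanine():
    oset = fx.insertion_ortholog_set()
    (ins,) = detect_tandem_insertion(oset)
    ev = infer_ancestral_unit(oset, ins)
    assert ev.ancestral_unit == fx.ANCESTRAL_ELEMENT
    assert ev.ancestral_unit_length == 12
    assert "minus 1 N-terminal" in ev.ancestral_unit_relation


@pytest.mark.parametrize("m", [4, 8, 12])
def test_planted_ancestral_element_length_recovered(m):
    ins_spec = InsertionSpec(unit_aa=fx.UNIT_CONSENSUS,
                             copies={"Ftri": 3, "Fbid": 3},
                             after_col=60, element_len=m)
    cfg = SimConfig(seed=m, subst_rate=0.0, root_length=120,
                    insertion=ins_spec)
    oset, _ = simulate_ortholog_set(cfg)
    (ins,) = detect_tandem_insertion(oset)
    ev = infer_ancestral_unit(oset, ins)
    assert ev.ancestral_unit_length == m
    assert ev.ancestral_unit == fx.UNIT_CONSENSUS[-m:]


def test_no_shared_element_returns_empty():
    aln = _aln_with_insertion({"car1": "DEK" * 3}, flank_a="MKTE",
                              flank_b="WYHC")
    (ins,) = detect_tandem_insertion(aln)
    ev = infer_ancestral_unit(aln, ins)
    assert ev.ancestral_unit is None
    assert ev.ancestral_unit_length == 0


# ---------------------------------------------------------------------------
# flanking direct repeats

def _oracle_flank(region, max_len=30):
    best = ("", 0)
    for L in range(1, min(max_len, len(region) // 2) + 1):
        if all(region[i] == region[len(region) - L + i] for i in range(L)):
            best = (region[:L], L)
    return best


def test_segment15_flank_is_gcggcg():
    assert find_flanking_direct_repeats(fx.SEGMENT15_CDS) == ("GCGGCG", 6)


def test_no_shared_word_gives_zero():
    assert find_flanking_direct_repeats("AAAACCCCTTTT") == ("", 0)


@pytest.mark.parametrize("seed", range(10))
def test_planted_flanks_match_naive_oracle(seed):
    rng = np.random.default_rng(seed)
    L = int(rng.integers(1, 12))
    flank = "".join(rng.choice(list("ACGT"), size=L))
    middle = "".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 40))))
    region = flank + middle + flank
    got = find_flanking_direct_repeats(region)
    assert got == _oracle_flank(region)
    assert got[1] >= L


# ---------------------------------------------------------------------------
# Nussinov maximum pairing

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
          ("G", "T"), ("T", "G")}


def _all_structures(seq, i, j, min_loop):
    if i >= j:
        yield frozenset()
        return
    yield from _all_structures(seq, i + 1, j, min_loop)
    for k in range(i + min_loop + 1, j + 1):
        if (seq[i], seq[k]) in _PAIRS:
            for inner in _all_structures(seq, i + 1, k - 1, min_loop):
                for outer in _all_structures(seq, k + 1, j, min_loop):
                    yield frozenset({(i, k)}) | inner | outer


def _oracle_max_pairs(seq, min_loop=3):
    return max(len(s) for s in _all_structures(seq, 0, len(seq) - 1, min_loop))


@pytest.mark.parametrize("seq", [
    "GGGAAACCC", "AAAAAA", "GCGCGCGCGC", "ATATATAT", "ACGTACGTACGT",
])
def test_nussinov_equals_structure_enumeration(seq):
    pairs, structure, _ = nussinov_hairpin(seq)
    assert pairs == _oracle_max_pairs(seq)
    # returned structure is well-formed and achieves the count
    stack, n_pairs = [], 0
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            i = stack.pop()
            assert (seq[i], seq[idx]) in _PAIRS
            assert idx - i > 3
            n_pairs += 1
    assert not stack and n_pairs == pairs


def test_nussinov_random_sequences_match_oracle(rng):
    for _ in range(8):
        n = int(rng.integers(6, 13))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        assert nussinov_hairpin(seq)[0] == _oracle_max_pairs(seq)


def test_nussinov_examples_and_wobble_switch():
    assert nussinov_hairpin("GGGAAACCC")[0] == 3
    assert nussinov_hairpin("AAAAAA")[0] == 0
    assert nussinov_hairpin("GGGGTTTT", allow_gu=False)[0] == 0
    assert nussinov_hairpin("GGGGTTTT", allow_gu=True)[0] >= 1


def test_element_cds_is_hairpin_capable():
    pairs, _, capable = nussinov_hairpin(fx.ELEMENT_DNA)
    assert capable
    assert pairs >= 6  # >= ceil(36/6)


# ---------------------------------------------------------------------------
# report assembly

def test_slippage_report_round_trips_and_links_evidence():
    oset = fx.insertion_ortholog_set()
    (ins,) = detect_tandem_insertion(oset)
    ev = infer_ancestral_unit(oset, ins)
    lo, hi = ins.insertion_column_span
    region = segment_cds(oset, "Fram", lo - ev.ancestral_unit_length, hi + 3)
    ev.flank_repeat_seq, ev.flank_repeat_len_bp = \
        find_flanking_direct_repeats(region)
    ev.hairpin_pairs, ev.hairpin_structure, ev.hairpin_capable = \
        nussinov_hairpin(fx.ELEMENT_DNA)
    rec = slippage_report(ins, ev, origin_node="N7")
    assert rec["insertion"]["unit_length_aa"] == 13
    assert rec["evidence"]["flank_repeat_seq"] == "GCGGCG"
    assert rec["origin_node"] == "N7"
    assert rec["interpretation"] is not None
    import json
    assert json.loads(json.dumps(rec)) == rec


def test_report_with_no_evidence_components():
    ins = RepeatInsertion(
        carrier_species=["x"], insertion_column_span=(5, 8),
        unit_length_aa=4, copies={"x": 1}, consensus_unit="DEKA",
        variant_sites=[], total_span_aa={"x": 4}, repetitive=False)
    rec = slippage_report(ins, SlippageEvidence())
    assert rec["interpretation"] is None
    assert rec["evidence"]["ancestral_unit"] is None
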