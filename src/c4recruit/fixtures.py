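"""Synthetic reconstructions of the motivating sequence examples.

The original alignments are not bundled, so these builders reconstruct
the described structure exactly: a clade-A-specific
insertion of four or five tandem 13-aa elements (consensus AAASVPDSADGGY,
variant at four unit positions), a 12-aa ancestral element present in all
species immediately N-terminal of the insertion, a following alanine
triplet whose coding DNA carries the direct repeat GCGGCG at the head and
tail of the 15-aa segment, and a mesophyll-expression-module (MEM1) B
submodule made of two copies of AAAACAAACAAAAAC within a 44-bp window.
Everything outside those described features (linker residues, promoter
background) is synthetic filler and is labelled as such.
"""

from __future__ import annotations

import numpy as np

from .seq_core import Alignment, OrthologSet, SeqRecord
from .synthetic_data import (BACKMAP, DEFAULT_PTYPES, PlantedMod, SimConfig,
                             InsertionSpec, default_tree,
                             simulate_ortholog_set)

# 13-aa tandem unit: consensus with variants at unit positions 3, 8, 10, 13
UNIT_CONSENSUS = "AAASVPDSADGGY"
UNIT_VARIANTS = {3: "P", 8: "K", 10: "Y", 13: "D"}

#: the expansion seed: the unit minus its N-terminal alanine
ANCESTRAL_ELEMENT = UNIT_CONSENSUS[1:]  # AASVPDSADGGY, 12 aa

#: element CDS pinned so the 15-aa segment is flanked by GCGGCG
ELEMENT_DNA = "GCG GCG AGC GTG CCG GAT AGC GCG GAT GGT GGT TAT".replace(" ", "")
TRIPLET_ALA = "AAA"
TRIPLET_ALA_DNA = "GCGGCGGCG"
#: CDS of the 15-aa segment (12-aa element + alanine triplet)
SEGMENT15_CDS = ELEMENT_DNA + TRIPLET_ALA_DNA

#: carriers of the clade-A insertion and their copy numbers
INSERTION_COPIES = {"Fpal": 4, "Fbid": 4, "Ftri": 4, "Faus": 4,
                    "Fvag": 5, "Fkoc": 5}

_VARIANT_CODON = {"P": "CCG", "K": "AAA", "Y": "TAT", "D": "GAT"}

# synthetic filler flanks (no structure of interest)
_UPSTREAM = "MKTESGVLNDRAQPFWHYCI"
_DOWNSTREAM = "LGKEDSVTRANQFYWHPMCI"


def _unit_copy(copy_index: int) -> str:
    """Copy 0 is the consensus; copies 1-4 carry one variant site each."""
    unit = list(UNIT_CONSENSUS)
    positions = sorted(UNIT_VARIANTS)
    if 1 <= copy_index <= len(positions):
        pos = positions[copy_index - 1]
        unit[pos - 1] = UNIT_VARIANTS[pos]
    return "".join(unit)


def _unit_copy_dna(copy_index: int) -> str:
    aa = _unit_copy(copy_index)
    base = "GCG" + ELEMENT_DNA  # consensus unit = A + element
    codons = [base[3 * k: 3 * k + 3] for k in range(len(UNIT_CONSENSUS))]
    for k, (a_cons, a_here) in enumerate(zip(UNIT_CONSENSUS, aa)):
        if a_here != a_cons:
            codons[k] = _VARIANT_CODON[a_here]
    return "".join(codons)


def insertion_ortholog_set() -> OrthologSet:
    """16-species protein alignment + CDS around the clade-A insertion.

    Layout per row: synthetic upstream flank, the 12-aa ancestral element
    (all species), the insertion span (65 columns: five 13-aa copies;
    4-copy carriers gap the last 13, non-carriers gap all 65), the
    alanine triplet, synthetic downstream flank.
    """
    tree = default_tree()
    unit_len = len(UNIT_CONSENSUS)
    span_cols = 5 * unit_len
    records = []
    cds = {}
    for sp in sorted(tree.tip_names):
        copies = INSERTION_COPIES.get(sp, 0)
        inserted = "".join(_unit_copy(i) for i in range(copies))
        inserted_dna = "".join(_unit_copy_dna(i) for i in range(copies))
        row = (_UPSTREAM + ANCESTRAL_ELEMENT + inserted
               + "-" * (span_cols - len(inserted)) + TRIPLET_ALA + _DOWNSTREAM)
        protein = row.replace("-", "")
        dna = ("".join(BACKMAP[a] for a in _UPSTREAM)
               + ELEMENT_DNA + inserted_dna + TRIPLET_ALA_DNA
               + "".join(BACKMAP[a] for a in _DOWNSTREAM))
        ptype = DEFAULT_PTYPES[sp]
        records.append(SeqRecord(id=sp, residues=row, molecule="protein",
                                 species=sp, ptype=ptype))
        cds[sp] = SeqRecord(id=sp, residues=dna, molecule="dna",
                            species=sp, ptype=ptype)
        assert len(protein) * 3 == len(dna)
    return OrthologSet(protein_alignment=Alignment(records=tuple(records)),
                       cds=cds, tree=tree)


def insertion_pairwise_alignment(carrier: str = "Ftri",
                            noncarrier: str = "Fcro") -> Alignment:
    """Two-row view (one carrier vs one C3 non-carrier) of the fixture.

    Columns where both rows are gaps (the unused fifth-copy slot for
    4-copy carriers) are dropped so the pair is a proper alignment.
    """
    full = insertion_ortholog_set().protein_alignment
    a = full.by_species(carrier).residues
    b = full.by_species(noncarrier).residues
    keep = [i for i in range(len(a)) if not (a[i] == "-" and b[i] == "-")]
    rec_a = SeqRecord(id=carrier, residues="".join(a[i] for i in keep),
                      molecule="protein", species=carrier,
                      ptype=DEFAULT_PTYPES[carrier])
    rec_b = SeqRecord(id=noncarrier, residues="".join(b[i] for i in keep),
                      molecule="protein", species=noncarrier,
                      ptype=DEFAULT_PTYPES[noncarrier])
    return Alignment(records=(rec_a, rec_b))


def insertion_presence_states() -> dict[str, str]:
    """Tip presence/absence of the insertion, for origin mapping."""
    return {sp: ("present" if sp in INSERTION_COPIES else "absent")
            for sp in DEFAULT_PTYPES}


# ---------------------------------------------------------------------------
# MEM1 B submodule (promoter side)

MEM1_B_CORE_SEQ = "AAAACAAACAAAAAC"
#: synthetic 14-bp spacer between the two core copies (44 bp total region)
_MEM1_SPACER = "TTGATTCGTGTAAT"
#: reconstruction of the two-copies-in-44-bp submodule region
MEM1_B_REGION = MEM1_B_CORE_SEQ + _MEM1_SPACER + MEM1_B_CORE_SEQ

MEM1_B_OFFSET = -2783  # signed start of the region, bp upstream of ATG


def mem1_promoter(length: int = 3000, seed: int = 1851) -> str:
    """Synthetic promoter carrying the MEM1 B region at its distal offset.

    AT-rich random background (GC 0.3) with the 44-bp two-copy submodule
    planted so its first base sits at offset −2783 from the start codon.
    """
    rng = np.random.default_rng(seed)
    probs = [0.35, 0.15, 0.15, 0.35]
    seq = list(rng.choice(list("ACGT"), size=length, p=probs))
    i = length + MEM1_B_OFFSET
    seq[i:i + len(MEM1_B_REGION)] = list(MEM1_B_REGION)
    out = "".join(seq)
    # background must not fake extra exact core hits
    assert out.count(MEM1_B_CORE_SEQ) == 2
    return out


# ---------------------------------------------------------------------------
# noise-free demo ortholog sets with planted modification counts

def _demo_mods(n: int, length: int, seed: int,
               exclude: tuple[int, int] | None = None) -> list[PlantedMod]:
    rng = np.random.default_rng(seed)
    pool = np.arange(30, length - 30)
    if exclude is not None:
        pool = pool[(pool < exclude[0]) | (pool > exclude[1])]
    cols = sorted(rng.choice(pool, size=n, replace=False))
    aa = "ACDEFGHIKLMNPQRSTVWY"
    mods = []
    for c in cols:
        i, j = rng.choice(20, size=2, replace=False)
        mods.append(PlantedMod(column=int(c), ancestral=aa[i], derived=aa[j],
                               origin_node="N7"))
    return mods


def ppt1_like_ortholog_set() -> tuple[OrthologSet, dict]:
    """Drift-free 406-aa demo set with 19 planted consistent modifications
    and the clade-A tandem insertion (synthetic stand-in for the PPT1
    ortholog set)."""
    cfg = SimConfig(
        seed=19, subst_rate=0.0, root_length=406,
        planted_mods=_demo_mods(19, 406, seed=19, exclude=(185, 205)),
        insertion=InsertionSpec(
            unit_aa=UNIT_CONSENSUS,
            copies=dict(INSERTION_COPIES),
            after_col=200,
            unit_dna="GCG" + ELEMENT_DNA,
            element_len=len(ANCESTRAL_ELEMENT),
            element_dna=ELEMENT_DNA,
        ),
    )
    return simulate_ortholog_set(cfg)


def ppt2_like_ortholog_set() -> tuple[OrthologSet, dict]:
    """Drift-free 417-aa demo set with 8 planted consistent modifications
    and no insertion (synthetic stand-in for the PPT2 ortholog set)."""
    cfg = SimConfig(seed=8, subst_rate=0.0, root_length=417,
                    planted_mods=_demo_mods(8, 417, seed=8))
    return simulate_ortholog_set(cfg)
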