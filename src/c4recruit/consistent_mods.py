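"""Consistent amino-acid modifications between C3 and C4 species.

A *consistent modification* is an alignment column fixed for one state in
every C3 species and fixed for a different state in every C4 species.
Intermediate photosynthetic types never veto consistency; they only inform
where on the tree the derived state arose, which is mapped with Fitch
small parsimony.

Gap handling: by default the gap is a 21st character state, columns that are
gap in every grouped species are skipped, and columns that form a
group-specific insertion (all-gap in one group, all residues in the other)
are excluded here — they are the substrate of the tandem-repeat detector,
not point modifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seq_core import GAP, Alignment, PhyloTree, TreeNode


@dataclass(frozen=True)
class ConsistentModification:
    column: int  # 1-based alignment column
    c3_state: str
    c4_state: str
    origin_node: str | None = None
    supporting_species: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.c3_state == self.c4_state:
            raise ValueError("modification requires c3_state != c4_state")


def species_by_ptype(records) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for r in records:
        out.setdefault(r.ptype, set()).add(r.species)
    return out


def group_specific_insertion_columns(aln: Alignment, c3: set[str],
                                     c4: set[str]) -> set[int]:
    """Columns all-gap in one group and all-residue in the other (1-based)."""
    out: set[int] = set()
    for col in range(1, aln.n_cols + 1):
        states = aln.column(col)
        s3 = [states[s] for s in c3]
        s4 = [states[s] for s in c4]
        gap3 = all(x == GAP for x in s3)
        gap4 = all(x == GAP for x in s4)
        res3 = all(x != GAP for x in s3)
        res4 = all(x != GAP for x in s4)
        if (gap3 and res4) or (gap4 and res3):
            out.add(col)
    return out


def classify_columns(aln: Alignment, c3: set[str], c4: set[str],
                     gap_policy: str = "state",
                     exclude_insertion_spans: bool = True,
                     ) -> list[ConsistentModification]:
    """Columns fixed within C3 and within C4 for two different states.

    gap_policy:
      * ``"state"`` (default) — gap is a 21st state; all-gap columns skipped.
      * ``"skip"`` — any gap in a grouped species drops the column.
    """
    if gap_policy not in ("state", "skip"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    c3, c4 = set(c3), set(c4)
    if c3 & c4:
        raise ValueError(f"groups overlap: {sorted(c3 & c4)}")
    for name, grp in (("C3", c3), ("C4", c4)):
        if len(grp) < 2:
            raise ValueError(f"{name} group needs >= 2 species, got {sorted(grp)}")
        missing = grp - set(aln.species)
        if missing:
            raise ValueError(f"{name} species missing from alignment: {sorted(missing)}")

    skip_cols = (group_specific_insertion_columns(aln, c3, c4)
                 if exclude_insertion_spans else set())
    mods: list[ConsistentModification] = []
    for col in range(1, aln.n_cols + 1):
        if col in skip_cols:
            continue
        states = aln.column(col)
        s3 = {states[s] for s in c3}
        s4 = {states[s] for s in c4}
        if gap_policy == "skip" and GAP in (s3 | s4):
            continue
        if s3 == {GAP} and s4 == {GAP}:
            continue
        if len(s3) == 1 and len(s4) == 1 and s3 != s4:
            a3, a4 = next(iter(s3)), next(iter(s4))
            mods.append(ConsistentModification(
                column=col, c3_state=a3, c4_state=a4,
                supporting_species={"C3": sorted(c3), "C4": sorted(c4)}))
    return mods


# ---------------------------------------------------------------------------
# Fitch small parsimony and origin mapping

def fitch(tree: PhyloTree, tip_states: dict[str, str],
          prefer_root_state: str | None = None,
          ) -> tuple[int, dict[str, str]]:
    """Minimum-change labeling of internal nodes (Fitch, rooted).

    Returns (parsimony score, node id -> state). Ambiguity is resolved
    deterministically: the root prefers *prefer_root_state* when optimal,
    otherwise the lexicographically first optimal state; children inherit
    the parental state whenever it is in their Fitch set.
    """
    missing = tree.tip_names - set(tip_states)
    if missing:
        raise ValueError(f"tips without states: {sorted(missing)}")

    sets: dict[int, frozenset[str]] = {}
    score = 0
    for node in tree.postorder():
        if node.is_tip:
            sets[id(node)] = frozenset({tip_states[node.id]})
        else:
            inter = None
            union: frozenset[str] = frozenset()
            for c in node.children:
                s = sets[id(c)]
                inter = s if inter is None else inter & s
                union |= s
            if inter:
                sets[id(node)] = inter
            else:
                # Fitch counts one change per empty pairwise intersection as
                # folded into the union step; with multifurcations this is
                # the standard generalization (Hartigan would be exact).
                sets[id(node)] = union
                score += 1
            # binary-tree exact accounting: one change where the two child
            # sets are disjoint; handled by the union branch above.

    labels: dict[str, str] = {}
    root_set = sets[id(tree.root)]
    if prefer_root_state is not None and prefer_root_state in root_set:
        labels[tree.root.id] = prefer_root_state
    else:
        labels[tree.root.id] = min(root_set)
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_state = labels[node.parent.id]
        s = sets[id(node)]
        labels[node.id] = parent_state if parent_state in s else min(s)
    return score, labels


def map_origin_node(tree: PhyloTree, tip_states: dict[str, str],
                    derived_state: str | None = None,
                    ancestral_state: str | None = None) -> str:
    """Node at which a derived state became fixed, under minimal change.

    With a single gain the result is the stem node of the derived clade;
    with homoplasy the origin covering the most derived tips is reported
    (ties broken toward the root by preorder). The root is biased toward
    the ancestral state when ambiguous, so a tip-restricted state maps to
    the pendant node, not the root.
    """
    states = set(tip_states.values())
    if len(states) < 2:
        raise ValueError("need >= 2 distinct tip states to map an origin")
    if derived_state is None:
        if len(states) != 2:
            raise ValueError("derived_state required when > 2 states present")
        if ancestral_state is not None:
            derived_state = next(iter(states - {ancestral_state}))
        else:
            # minority state is taken as derived
            counts = {s: sum(1 for v in tip_states.values() if v == s)
                      for s in states}
            derived_state = min(counts, key=lambda s: (counts[s], s))
    if ancestral_state is None:
        anc_candidates = states - {derived_state}
        ancestral_state = min(anc_candidates) if anc_candidates else None

    _, labels = fitch(tree, tip_states, prefer_root_state=ancestral_state)
    origins: list[TreeNode] = []
    for node in tree.preorder():
        if labels[node.id] != derived_state:
            continue
        if node.parent is None or labels[node.parent.id] != derived_state:
            origins.append(node)
    if not origins:
        raise ValueError(f"derived state {derived_state!r} never assigned")

    def coverage(n: TreeNode) -> int:
        return sum(1 for t in tree.tips_under(n)
                   if tip_states[t] == derived_state)

    best = max(origins, key=coverage)  # preorder keeps root-most on ties
    return best.id


def map_modification_origins(tree: PhyloTree, aln: Alignment,
                             mods: list[ConsistentModification],
                             ) -> list[ConsistentModification]:
    """Attach a Fitch origin node to each modification (derived = C4 state)."""
    out = []
    for m in mods:
        tip_states = aln.column(m.column)
        tip_states = {t: tip_states.get(t, m.c3_state) for t in tree.tip_names}
        origin = map_origin_node(tree, tip_states, derived_state=m.c4_state,
                                 ancestral_state=m.c3_state)
        out.append(ConsistentModification(
            column=m.column, c3_state=m.c3_state, c4_state=m.c4_state,
            origin_node=origin, supporting_species=m.supporting_species))
    return out


# ---------------------------------------------------------------------------
# reporting

def mods_table(mods: list[ConsistentModification]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.column, m.c3_state, m.c4_state, m.origin_node or "") for m in mods],
        columns=["column", "c3_state", "c4_state", "origin_node"],
    )


def count_report(mods_per_gene: dict[str, list[ConsistentModification]],
                 ) -> pd.DataFrame:
    """Per-gene count of consistent modifications."""
    rows = [(gene, len(mods)) for gene, mods in mods_per_gene.items()]
    return pd.DataFrame(rows, columns=["gene", "n_consistent_modifications"])
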