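"""Sequence and tree data model shared by every analysis stage.

Thin domain wrappers around Biopython (FASTA) and DendroPy (Newick): records
carry a species name and a photosynthetic-type label (``C3``, ``C3-C4-I``,
``C3-C4-II``, ``C4-like``, ``C4`` or ``NA``) because every downstream
comparison is stratified by photosynthetic type.

Coordinate conventions: alignment columns are 1-based throughout the public
API; the gap character is ``-`` only (the ``.`` dialect is rejected).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

PTYPES = frozenset({"C3", "C3-C4-I", "C3-C4-II", "C4-like", "C4", "NA"})

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
DNA_ALPHABET = frozenset("ACGT")
GAP = "-"


class FormatError(ValueError):
    """Malformed input file or record."""


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence with species and photosynthetic-type annotation."""

    id: str
    residues: str
    molecule: str  # "protein" | "dna"
    species: str = ""
    ptype: str = "NA"

    def __post_init__(self):
        if self.molecule not in ("protein", "dna"):
            raise ValueError(f"unknown molecule {self.molecule!r}")
        if not self.residues:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.ptype not in PTYPES:
            raise ValueError(f"record {self.id!r}: unknown ptype {self.ptype!r}")
        if not self.species:
            object.__setattr__(self, "species", self.id)
        alpha = PROTEIN_ALPHABET if self.molecule == "protein" else DNA_ALPHABET
        for i, ch in enumerate(self.residues):
            if ch == GAP:
                continue
            if ch == ".":
                raise FormatError(
                    f"record {self.id!r}: '.' gap at position {i + 1}; only '-' is accepted"
                )
            if ch not in alpha:
                raise FormatError(
                    f"record {self.id!r}: illegal {self.molecule} character "
                    f"{ch!r} at position {i + 1}"
                )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """An ordered multiple alignment; all records share one length."""

    records: tuple[SeqRecord, ...]

    def __post_init__(self):
        if len(self.records) < 2:
            raise ValueError("alignment needs >= 2 records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")

    @property
    def n_cols(self) -> int:
        return len(self.records[0])

    def column(self, col: int) -> dict[str, str]:
        """States of 1-based column *col*, keyed by species."""
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} outside 1..{self.n_cols}")
        return {r.species: r.residues[col - 1] for r in self.records}

    def by_species(self, species: str) -> SeqRecord:
        for r in self.records:
            if r.species == species:
                return r
        raise KeyError(f"species {species!r} not in alignment")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(r.species for r in self.records)


# ---------------------------------------------------------------------------
# trees


class TreeNode:
    """Node of a rooted phylogeny; tips carry species names as ids."""

    __slots__ = ("id", "length", "children", "parent", "_auto_id")

    def __init__(self, id: str, length: float = 0.0, auto_id: bool = False):
        self.id = id
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self._auto_id = auto_id

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"TreeNode({self.id!r})"


class PhyloTree:
    """Rooted tree with unique tip names and optional internal labels."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = [n.id for n in self.postorder() if n.is_tip]
        if len(names) != len(set(names)):
            raise FormatError("duplicate tip names in tree")
        seen: set[str] = set()
        counter = 0
        for node in self.postorder():
            if node.id is None or node.id == "":
                counter += 1
                node.id = f"_nd{counter}"
                node._auto_id = True
            if node.id in seen:
                raise FormatError(f"duplicate node id {node.id!r}")
            seen.add(node.id)

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(n: TreeNode):
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return out

    def preorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(n.children))
        return out

    @property
    def tip_names(self) -> set[str]:
        return {n.id for n in self.postorder() if n.is_tip}

    def node(self, node_id: str) -> TreeNode:
        for n in self.postorder():
            if n.id == node_id:
                return n
        raise KeyError(f"no node {node_id!r}")

    def tips_under(self, node: TreeNode | str) -> set[str]:
        if isinstance(node, str):
            node = self.node(node)
        return {n.id for n in _subtree_postorder(node) if n.is_tip}

    def copy(self) -> "PhyloTree":
        return read_newick_string(write_newick_string(self))


def _subtree_postorder(node: TreeNode) -> list[TreeNode]:
    out: list[TreeNode] = []

    def walk(n: TreeNode):
        for c in n.children:
            walk(c)
        out.append(n)

    walk(node)
    return out


def _from_dendropy(dnode, parent=None) -> TreeNode:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon else dnode.label
    else:
        label = dnode.label
    n = TreeNode(label, float(dnode.edge.length or 0.0))
    if n.length < 0:
        raise FormatError(f"negative branch length at {label!r}")
    n.parent = parent
    for c in dnode.child_nodes():
        child = _from_dendropy(c, n)
        n.children.append(child)
    return n


def read_newick_string(text: str) -> PhyloTree:
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"bad newick: {exc}") from exc
    return PhyloTree(_from_dendropy(dtree.seed_node))


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return read_newick_string(fh.read())


def _newick_of(node: TreeNode) -> str:
    label = "" if node._auto_id else node.id
    if node.is_tip:
        return f"{label}:{node.length:g}"
    inner = ",".join(_newick_of(c) for c in node.children)
    return f"({inner}){label}:{node.length:g}"


def write_newick_string(tree: PhyloTree) -> str:
    root = tree.root
    label = "" if root._auto_id else root.id
    inner = ",".join(_newick_of(c) for c in root.children)
    return f"({inner}){label};\n"


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick_string(tree))


# ---------------------------------------------------------------------------
# FASTA I/O

def _parse_header(header: str) -> tuple[str, str, str]:
    """Split ``id|species|ptype`` headers; missing tokens default sensibly."""
    parts = header.split("|")
    rid = parts[0].strip()
    species = parts[1].strip() if len(parts) > 1 and parts[1].strip() else rid
    ptype = parts[2].strip() if len(parts) > 2 and parts[2].strip() else "NA"
    return rid, species, ptype


def read_fasta(path, molecule: str) -> list[SeqRecord]:
    """Read FASTA records, normalizing case and stripping terminal ``*``.

    Headers may carry ``id|species|ptype`` tokens; a sidecar metadata TSV
    (see :func:`read_metadata`) overrides header-derived labels.
    """
    try:
        bio = list(SeqIO.parse(path, "fasta"))
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not bio:
        raise FormatError(f"{path}: no FASTA records")
    out: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in bio:
        rid, species, ptype = _parse_header(rec.description or rec.id)
        if rid in seen:
            raise FormatError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            warnings.warn(f"record {rid!r}: stripped terminal '*'", stacklevel=2)
            seq = seq[:-1]
        if "*" in seq:
            raise FormatError(
                f"record {rid!r}: internal '*' at position {seq.index('*') + 1}"
            )
        out.append(SeqRecord(id=rid, residues=seq, molecule=molecule,
                             species=species, ptype=ptype))
    return out


def write_fasta(records, path, width: int = 60) -> None:
    bio = []
    for r in records:
        header = f"{r.id}|{r.species}|{r.ptype}"
        bio.append(_BioRecord(Seq(r.residues), id=header, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_metadata(path) -> dict[str, tuple[str, str]]:
    """Sidecar TSV with columns id, species, ptype (header row required)."""
    import csv

    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        need = {"id", "species", "ptype"}
        if reader.fieldnames is None or not need <= set(reader.fieldnames):
            raise FormatError(f"{path}: metadata TSV needs columns {sorted(need)}")
        for row in reader:
            out[row["id"]] = (row["species"], row["ptype"])
    return out


def apply_metadata(records, meta) -> list[SeqRecord]:
    """Overlay sidecar metadata on records; the sidecar wins on conflict."""
    out = []
    for r in records:
        if r.id in meta:
            species, ptype = meta[r.id]
            r = replace(r, species=species or r.species, ptype=ptype or r.ptype)
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# translation

def translate_cds(dna: SeqRecord) -> SeqRecord:
    """Standard-code translation; terminal stop stripped, internal stop fatal."""
    if dna.molecule != "dna":
        raise ValueError("translate_cds needs a DNA record")
    seq = dna.ungapped
    if len(seq) % 3:
        raise FormatError(
            f"record {dna.id!r}: CDS length {len(seq)} not divisible by 3"
        )
    prot = str(Seq(seq).translate(table=1))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise FormatError(
            f"record {dna.id!r}: internal stop codon at codon {prot.index('*') + 1}"
        )
    if not prot:
        raise FormatError(f"record {dna.id!r}: nothing left after stop removal")
    return SeqRecord(id=dna.id, residues=prot, molecule="protein",
                     species=dna.species, ptype=dna.ptype)


# ---------------------------------------------------------------------------
# global alignment / identity

def needleman_wunsch(a: str, b: str, match: float = 1.0, mismatch: float = 0.0,
                     gap: float = -1.0) -> tuple[str, str, float]:
    """Global alignment with linear gap cost and deterministic traceback.

    Ties are broken diagonal > up (gap in *b*) > left (gap in *a*), so the
    same inputs always yield the same alignment.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * gap
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        ai = a[i - 1]
        row, prev = score[i], score[i - 1]
        for j in range(1, m + 1):
            d = prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            u = prev[j] + gap
            l = row[j - 1] + gap
            row[j] = d if d >= u and d >= l else (u if u >= l else l)
    # traceback, diag > up > left
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        here = score[i][j]
        if i > 0 and j > 0:
            d = score[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            if d == here:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and score[i - 1][j] + gap == here:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
            continue
        out_a.append(GAP)
        out_b.append(b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score[n][m]


def global_identity(a, b, match: float = 1.0, mismatch: float = 0.0,
                    gap: float = -1.0) -> float:
    """Percent identity over a Needleman–Wunsch global alignment.

    identity = matched columns / alignment length x 100.
    """
    sa = a.residues if isinstance(a, SeqRecord) else a
    sb = b.residues if isinstance(b, SeqRecord) else b
    if isinstance(a, SeqRecord) and isinstance(b, SeqRecord):
        if a.molecule != b.molecule:
            raise ValueError("cannot compare mixed molecules")
    if not sa or not sb:
        raise ValueError("empty sequence")
    aln_a, aln_b, _ = needleman_wunsch(sa, sb, match, mismatch, gap)
    matches = sum(1 for x, y in zip(aln_a, aln_b) if x == y and x != GAP)
    return 100.0 * matches / len(aln_a)


# ---------------------------------------------------------------------------
# ortholog set

@dataclass
class OrthologSet:
    """Protein alignment + per-species CDS + species tree, cross-validated."""

    protein_alignment: Alignment
    cds: dict[str, SeqRecord]
    tree: PhyloTree

    def __post_init__(self):
        tips = self.tree.tip_names
        for rec in self.protein_alignment.records:
            if rec.species not in tips:
                raise ValueError(
                    f"species {rec.species!r} in alignment but not in tree "
                    f"(tips: {sorted(tips)})"
                )
            if rec.species in self.cds:
                prot = translate_cds(self.cds[rec.species])
                if prot.residues != rec.ungapped:
                    raise ValueError(
                        f"species {rec.species!r}: CDS translation disagrees "
                        "with ungapped protein"
                    )

    @property
    def species(self) -> tuple[str, ...]:
        return self.protein_alignment.species
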