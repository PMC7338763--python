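"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is deterministic under a fixed seed and returns a truth
table alongside the data, so downstream stages can be tested for exact
recovery of what was planted. The default study conditions emulate a
16-species Flaveria-like ortholog set: a two-clade tree whose clade-A
C4-like/C4 stem is named "N7", point modifications planted on that stem,
a tandem 13-aa insertion carried by the N7 clade, promoters with planted
cis-elements, log-normal expression with a leaf/root and MC/BSC dominance
switch, and light-induction time courses sampled at 0, 0.5, 2 and 4 h.

Protein evolution uses a uniform substitution kernel over the 20 amino
acids: the downstream consistency classifier is alphabet-agnostic, so an
empirical exchangeability matrix would add realism without changing what
the tests can detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression_shift import ExpressionMatrix, LightSeries, QpcrRecord
from .seq_core import (Alignment, OrthologSet, PhyloTree, SeqRecord,
                       read_newick_string)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: lexicographically first standard-code codon per amino acid
BACKMAP = {
    "A": "GCA", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC", "G": "GGA",
    "H": "CAC", "I": "ATA", "K": "AAA", "L": "CTA", "M": "ATG", "N": "AAC",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "AGC", "T": "ACA", "V": "GTA",
    "W": "TGG", "Y": "TAC",
}

DEFAULT_TREE_NEWICK = (
    "((Fcro:0.05,(Fpri:0.04,Frob:0.04)N2:0.015)N1:0.02,"
    "((Fram:0.05,(Fpal:0.035,((Fkoc:0.02,Fvag:0.02)N8:0.015,"
    "(Faus:0.03,(Ftri:0.02,Fbid:0.02)N10:0.01)N9:0.008)N11:0.01)N7:0.02)N6:0.02,"
    "(Fson:0.04,(Fang:0.035,(Fano:0.03,(Fpub:0.025,(Fchl:0.02,Fbro:0.02)"
    "N16:0.01)N15:0.008)N14:0.008)N13:0.01)N12:0.025)N5:0.02)N0;"
)

DEFAULT_PTYPES = {
    "Fcro": "C3", "Fpri": "C3", "Frob": "C3",
    "Fson": "C3-C4-I", "Fang": "C3-C4-I", "Fano": "C3-C4-I",
    "Fpub": "C3-C4-I", "Fchl": "C3-C4-I",
    "Fram": "C3-C4-II",
    "Fpal": "C4-like", "Fvag": "C4-like", "Fbro": "C4-like",
    "Fkoc": "C4", "Faus": "C4", "Ftri": "C4", "Fbid": "C4",
}


def default_tree() -> PhyloTree:
    """Stylized two-clade 16-tip tree; node N7 is the clade-A C4-like/C4 stem."""
    return read_newick_string(DEFAULT_TREE_NEWICK)


def backmap_cds(protein: str) -> str:
    return "".join(BACKMAP[aa] for aa in protein)


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class PlantedMod:
    column: int  # 1-based column in the root protein
    ancestral: str
    derived: str
    origin_node: str = "N7"


@dataclass
class InsertionSpec:
    unit_aa: str
    copies: dict[str, int]  # carrier species -> copy count
    after_col: int  # insertion immediately after this root column
    unit_dna: str | None = None  # pinned CDS of the unit (3x unit length)
    element_len: int = 0  # ancestral element planted before the insertion
    element_dna: str | None = None


@dataclass
class PromoterSpec:
    length: int = 3000
    gc: float = 0.35
    promoter_ids: tuple[str, ...] = ("PPT1A_C4", "PPT1_C3")
    planted: list = field(default_factory=list)  # (promoter_id, motif, offset)


@dataclass
class Stratum:
    ptype: str
    tissue: str
    cell: str
    means: dict[str, float]  # gene -> linear-scale mean abundance


@dataclass
class ExpressionSpec:
    genes: tuple[str, ...] = ("PPT1", "PPT2")
    strata: list[Stratum] = field(default_factory=list)
    log_sd: float = 0.3  # sd of natural-log abundance
    replicates: int = 3


@dataclass
class LightSpec:
    times: tuple[float, ...] = (0.0, 0.5, 2.0, 4.0)
    fold_changes: tuple[float, ...] = (1.5, 2.0, 1.5)  # per interval
    baseline: float = 1.0
    replicates: int = 3
    noise_sd: float = 0.15  # sd of natural-log abundance


@dataclass
class QpcrSpec:
    reference_ct: float = 20.0  # ACTIN7-role reference gene
    noise_sd: float = 0.0  # per-well Ct noise


def default_expression_strata() -> list[Stratum]:
    """The qualitative C3/C4 dominance pattern with a 4x leaf/MC switch."""
    return [
        Stratum("C3", "leaf", "whole", {"PPT1": 20.0, "PPT2": 80.0}),
        Stratum("C3", "leaf", "MC", {"PPT1": 15.0, "PPT2": 70.0}),
        Stratum("C3", "leaf", "BSC", {"PPT1": 60.0, "PPT2": 30.0}),
        Stratum("C3", "root", "whole", {"PPT1": 80.0, "PPT2": 10.0}),
        Stratum("C4", "leaf", "whole", {"PPT1": 250.0, "PPT2": 70.0}),
        Stratum("C4", "leaf", "MC", {"PPT1": 300.0, "PPT2": 70.0}),
        Stratum("C4", "leaf", "BSC", {"PPT1": 80.0, "PPT2": 60.0}),
        Stratum("C4", "root", "whole", {"PPT1": 25.0, "PPT2": 15.0}),
    ]


@dataclass
class SimConfig:
    seed: int = 0
    tree: PhyloTree | None = None
    ptypes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PTYPES))
    root_protein: str | None = None
    root_length: int = 400
    subst_rate: float = 0.02  # substitutions / site / branch-length unit
    planted_mods: list[PlantedMod] = field(default_factory=list)
    insertion: InsertionSpec | None = None
    promoter: PromoterSpec = field(default_factory=PromoterSpec)
    expression: ExpressionSpec = field(
        default_factory=lambda: ExpressionSpec(strata=default_expression_strata()))
    light: LightSpec = field(default_factory=LightSpec)
    qpcr: QpcrSpec = field(default_factory=QpcrSpec)

    def __post_init__(self):
        if self.tree is None:
            self.tree = default_tree()


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, stream])


# ---------------------------------------------------------------------------
# ortholog sets

def simulate_ortholog_set(cfg: SimConfig) -> tuple[OrthologSet, dict]:
    """Evolve a protein down the tree, plant modifications and an insertion.

    Substitutions are Poisson with mean ``subst_rate x branch length`` per
    site, drawn uniformly over the other 19 residues. Planted
    modifications set the ancestral residue at the root and overwrite the
    derived residue on every tip descending from the origin node (other
    tips may still drift, which is what the recovery-rate tests measure).
    The insertion and any planted ancestral element are protected from
    drift so carriers stay exact tandem copies.
    """
    rng = _rng(cfg.seed, 1)
    tree = cfg.tree
    if cfg.root_protein is None:
        root = "".join(rng.choice(list(AA20), size=cfg.root_length))
    else:
        root = cfg.root_protein
    root = list(root)
    L = len(root)

    protected: set[int] = set()  # 0-based root positions excluded from drift
    ins = cfg.insertion
    if ins is not None:
        if not 0 <= ins.after_col <= L:
            raise ValueError("insertion column outside root protein")
        if ins.element_len:
            if ins.element_len > ins.after_col:
                raise ValueError("ancestral element does not fit before insertion")
            elem = ins.unit_aa[len(ins.unit_aa) - ins.element_len:]
            for k, aa in enumerate(elem):
                root[ins.after_col - ins.element_len + k] = aa
            protected |= set(range(ins.after_col - ins.element_len, ins.after_col))

    for mod in cfg.planted_mods:
        if not 1 <= mod.column <= L:
            raise ValueError(f"planted column {mod.column} outside root")
        if ins is not None and (mod.column - 1) in protected:
            raise ValueError(
                f"planted modification at column {mod.column} conflicts "
                "with the insertion's ancestral element")
        root[mod.column - 1] = mod.ancestral  # drift allowed: recovery is measured

    seqs: dict[int, list[str]] = {id(tree.root): root}
    for node in tree.preorder():
        if node is tree.root:
            continue
        seq = list(seqs[id(node.parent)])
        n_sub = rng.poisson(cfg.subst_rate * node.length * L)
        sites = rng.integers(0, L, size=n_sub)
        for s in sites:
            if s in protected:
                continue
            alternatives = [a for a in AA20 if a != seq[s]]
            seq[s] = alternatives[rng.integers(0, 19)]
        seqs[id(node)] = seq

    # planted modifications: derived state fixed below the origin node
    for mod in cfg.planted_mods:
        below = tree.tips_under(mod.origin_node)
        for node in tree.postorder():
            if node.is_tip and node.id in below:
                seqs[id(node)][mod.column - 1] = mod.derived

    # assemble aligned rows (insertion becomes gap columns in non-carriers)
    records = []
    cds: dict[str, SeqRecord] = {}
    max_copies = max(ins.copies.values()) if ins else 0
    unit_len = len(ins.unit_aa) if ins else 0
    span_cols = max_copies * unit_len
    truth_inserted: dict[str, str] = {}
    for node in tree.postorder():
        if not node.is_tip:
            continue
        sp = node.id
        base = "".join(seqs[id(node)])
        if ins is not None:
            k = ins.copies.get(sp, 0)
            inserted = ins.unit_aa * k
            truth_inserted[sp] = inserted
            row = (base[:ins.after_col] + inserted
                   + "-" * (span_cols - len(inserted)) + base[ins.after_col:])
            protein_ungapped = base[:ins.after_col] + inserted + base[ins.after_col:]
        else:
            row = base
            protein_ungapped = base
        ptype = cfg.ptypes.get(sp, "NA")
        records.append(SeqRecord(id=sp, residues=row, molecule="protein",
                                 species=sp, ptype=ptype))
        cds_seq = _backmap_with_pins(protein_ungapped, cfg, sp)
        cds[sp] = SeqRecord(id=sp, residues=cds_seq, molecule="dna",
                            species=sp, ptype=ptype)

    oset = OrthologSet(protein_alignment=Alignment(records=tuple(records)),
                       cds=cds, tree=tree)
    truth = {
        "planted_columns": [
            {"column": m.column + (span_cols if ins and m.column > ins.after_col
                                   else 0),
             "root_column": m.column,
             "ancestral": m.ancestral, "derived": m.derived,
             "origin_node": m.origin_node}
            for m in cfg.planted_mods],
        "insertion": None,
    }
    if ins is not None:
        truth["insertion"] = {
            "span": (ins.after_col + 1, ins.after_col + span_cols),
            "unit_aa": ins.unit_aa,
            "unit_length": unit_len,
            "copies": dict(ins.copies),
            "element_len": ins.element_len,
            "inserted": truth_inserted,
        }
    return oset, truth


def _backmap_with_pins(protein: str, cfg: SimConfig, species: str) -> str:
    codons = [BACKMAP[aa] for aa in protein]
    ins = cfg.insertion
    if ins is None:
        return "".join(codons)
    if ins.element_dna is not None and ins.element_len:
        start = ins.after_col - ins.element_len
        for k in range(ins.element_len):
            codons[start + k] = ins.element_dna[3 * k: 3 * k + 3]
    if ins.unit_dna is not None:
        k_copies = ins.copies.get(species, 0)
        u = len(ins.unit_aa)
        for c in range(k_copies):
            for k in range(u):
                codons[ins.after_col + c * u + k] = ins.unit_dna[3 * k: 3 * k + 3]
    return "".join(codons)


# ---------------------------------------------------------------------------
# promoters

def simulate_promoters(cfg: SimConfig) -> tuple[dict[str, str], list[dict]]:
    """Random-background promoters with motifs planted at signed offsets."""
    rng = _rng(cfg.seed, 2)
    spec = cfg.promoter
    if not 0 <= spec.gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    probs = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2,
                      (1 - spec.gc) / 2])
    promoters: dict[str, str] = {}
    for pid in spec.promoter_ids:
        draws = rng.choice(list("ACGT"), size=spec.length, p=probs)
        promoters[pid] = "".join(draws)
    truth = []
    for pid, motif, offset in spec.planted:
        if pid not in promoters:
            raise KeyError(f"unknown promoter id {pid!r}")
        seq = promoters[pid]
        if offset > -1 or -offset > len(seq):
            raise ValueError(f"offset {offset} outside promoter {pid!r}")
        i = len(seq) + offset
        if i + len(motif) > len(seq):
            raise ValueError(f"motif at {offset} overruns promoter {pid!r}")
        promoters[pid] = seq[:i] + motif + seq[i + len(motif):]
        truth.append({"promoter_id": pid, "motif": motif, "offset": offset})
    return promoters, truth


# ---------------------------------------------------------------------------
# expression matrices

def simulate_expression(cfg: SimConfig) -> tuple[ExpressionMatrix, dict]:
    """Log-normal abundances per stratum; truth records the dominance plan."""
    import pandas as pd

    rng = _rng(cfg.seed, 3)
    spec = cfg.expression
    strata = spec.strata or default_expression_strata()
    columns = {}
    meta_rows = []
    for st in strata:
        for rep in range(1, spec.replicates + 1):
            sample = f"{st.ptype}_{st.tissue}_{st.cell}_r{rep}"
            vals = []
            for gene in spec.genes:
                mu = st.means[gene]
                if spec.log_sd == 0:
                    vals.append(mu)
                else:
                    vals.append(mu * float(np.exp(rng.normal(0.0, spec.log_sd))))
            columns[sample] = vals
            meta_rows.append((sample, st.ptype, st.ptype, st.tissue, st.cell, rep))
    values = pd.DataFrame(columns, index=list(spec.genes))
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "species", "ptype", "tissue", "cell",
                            "replicate"]).set_index("sample")
    matrix = ExpressionMatrix(values=values, meta=meta, unit="TPM")
    truth = {"strata": [
        {"ptype": st.ptype, "tissue": st.tissue, "cell": st.cell,
         "dominant": max(st.means, key=st.means.get)} for st in strata]}
    dom = {(s["ptype"], s["tissue"], s["cell"]): s["dominant"]
           for s in truth["strata"]}
    truth["switch"] = (
        dom.get(("C3", "leaf", "whole")) != dom.get(("C4", "leaf", "whole")))
    truth["recruited_gene"] = dom.get(("C4", "leaf", "whole"))
    return matrix, truth


# ---------------------------------------------------------------------------
# light courses and qPCR

def simulate_light_course(cfg: SimConfig, gene: str = "PPT1",
                          ) -> tuple[LightSeries, dict]:
    """Replicate abundance series with configured per-interval fold changes."""
    rng = _rng(cfg.seed, 4)
    spec = cfg.light
    if len(spec.fold_changes) != len(spec.times) - 1:
        raise ValueError("need one fold change per consecutive interval")
    means = [spec.baseline]
    for f in spec.fold_changes:
        means.append(means[-1] * f)
    reps = {}
    for t, mu in zip(spec.times, means):
        if spec.noise_sd == 0:
            reps[t] = np.full(spec.replicates, mu)
        else:
            reps[t] = mu * np.exp(rng.normal(0.0, spec.noise_sd,
                                             size=spec.replicates))
    series = LightSeries(gene=gene, times=tuple(spec.times), replicates=reps)
    truth = {"means": dict(zip(spec.times, means)),
             "fold_changes": list(spec.fold_changes)}
    return series, truth


def simulate_qpcr_ct(cfg: SimConfig, abundances: dict[str, float] | None = None,
                     gene: str = "PPT1") -> tuple[list[QpcrRecord], dict]:
    """Ct tables from known relative abundances: Ct = ref_Ct - log2(a) + noise."""
    rng = _rng(cfg.seed, 5)
    spec = cfg.qpcr
    if abundances is None:
        abundances = {"s1": 1.0, "s2": 2.0, "s3": 0.5}
    records = []
    for sample, a in abundances.items():
        if a <= 0:
            raise ValueError("abundances must be positive")
        noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0
        ct = spec.reference_ct - float(np.log2(a)) + noise
        records.append(QpcrRecord(gene=gene, sample=sample, ct_target=ct,
                                  ct_reference=spec.reference_ct))
    return records, {"abundances": dict(abundances)}


# ---------------------------------------------------------------------------
# file emission

def write_ortholog_set(oset: OrthologSet, outdir) -> dict[str, str]:
    """FASTA + Newick + metadata TSV bundle for CLI hand-off."""
    import csv
    from pathlib import Path

    from .seq_core import write_fasta, write_newick

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein": str(outdir / "protein_aln.fasta"),
        "cds": str(outdir / "cds.fasta"),
        "tree": str(outdir / "tree.nwk"),
        "metadata": str(outdir / "metadata.tsv"),
    }
    write_fasta(oset.protein_alignment.records, paths["protein"])
    write_fasta([oset.cds[sp] for sp in sorted(oset.cds)], paths["cds"])
    write_newick(oset.tree, paths["tree"])
    with open(paths["metadata"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["id", "species", "ptype"])
        for rec in oset.protein_alignment.records:
            w.writerow([rec.id, rec.species, rec.ptype])
    return paths
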