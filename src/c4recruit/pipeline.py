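"""End-to-end orchestration: simulate/load inputs, run every stage, report.

All hand-off between stages is via files in the output directory; the
report bundle is deterministic under a fixed config + seed (no timestamps
inside outputs) and embeds the config and package version for provenance.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import fixtures
from .consistent_mods import (classify_columns, map_modification_origins,
                              map_origin_node, mods_table, species_by_ptype)
from .expression_shift import recruitment_switch, stepwise_light_test
from .promoter_modules import MEM1_B_CORE, scan_motif, submodule_present
from .repeat_slippage import (detect_tandem_insertion,
                              find_flanking_direct_repeats,
                              infer_ancestral_unit, nussinov_hairpin,
                              segment_cds, slippage_report)
from .seq_core import (Alignment, OrthologSet, apply_metadata, read_fasta,
                       read_metadata, read_newick)


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "c4recruit_out"
    demo: bool = True  # run on the bundled reconstructions
    protein_fasta: str | None = None
    cds_fasta: str | None = None
    tree: str | None = None
    metadata: str | None = None
    promoter_fasta: str | None = None
    c3: list[str] = field(default_factory=list)
    c4: list[str] = field(default_factory=list)
    include_c4_like: bool = False
    min_unit: int = 3
    max_unit: int = 50
    max_mismatch: int = 2
    run_expression: bool = True
    run_selection: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self):
        if not self.demo:
            for key in ("protein_fasta", "tree"):
                if getattr(self, key) is None:
                    raise ValueError(f"config missing {key!r} (demo=false)")
            if not self.c3 or not self.c4:
                raise ValueError("config missing C3/C4 group definitions")


def _log(msg: str):
    print(msg, file=sys.stderr)


def _load_inputs(cfg: RunConfig):
    if cfg.demo:
        oset = fixtures.insertion_ortholog_set()
        promoters = {"PPT1A_C4_promoter": fixtures.mem1_promoter()}
        return oset, promoters
    records = read_fasta(cfg.protein_fasta, "protein")
    if cfg.metadata:
        records = apply_metadata(records, read_metadata(cfg.metadata))
    aln = Alignment(records=tuple(records))
    tree = read_newick(cfg.tree)
    cds = {}
    if cfg.cds_fasta:
        for rec in read_fasta(cfg.cds_fasta, "dna"):
            cds[rec.species] = rec
    oset = OrthologSet(protein_alignment=aln, cds=cds, tree=tree)
    promoters = {}
    if cfg.promoter_fasta:
        for rec in read_fasta(cfg.promoter_fasta, "dna"):
            promoters[rec.id] = rec.residues
    return oset, promoters


def _groups(cfg: RunConfig, oset: OrthologSet) -> tuple[set, set]:
    if cfg.c3 and cfg.c4:
        return set(cfg.c3), set(cfg.c4)
    by_type = species_by_ptype(oset.protein_alignment.records)
    c3 = by_type.get("C3", set())
    c4 = set(by_type.get("C4", set()))
    if cfg.include_c4_like:
        c4 |= by_type.get("C4-like", set())
    return c3, c4


def run_all(cfg: RunConfig) -> dict:
    """Execute all stages; returns the report dict (also written to disk)."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
    report: dict = {
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(asdict(cfg), sort_keys=True).encode()).hexdigest(),
        "package_version": __import__("c4recruit").__version__,
        "seed": cfg.seed,
    }

    t0 = time.perf_counter()
    oset, promoters = _load_inputs(cfg)
    _log(f"[inputs] {len(oset.species)} species, "
         f"{oset.protein_alignment.n_cols} columns "
         f"({time.perf_counter() - t0:.2f}s)")

    # --- consistent modifications -------------------------------------
    t0 = time.perf_counter()
    c3, c4 = _groups(cfg, oset)
    mods = classify_columns(oset.protein_alignment, c3, c4)
    mods = map_modification_origins(oset.tree, oset.protein_alignment, mods)
    mods_table(mods).to_csv(out / "consistent_mods.tsv", sep="\t", index=False)
    report["consistent_mods"] = {
        "n": len(mods),
        "c3_group": sorted(c3), "c4_group": sorted(c4),
        "include_c4_like": cfg.include_c4_like,
        "gap_policy": "state",
    }
    _log(f"[consistent-mods] {len(mods)} columns "
         f"({time.perf_counter() - t0:.2f}s)")

    # --- repeats / slippage -------------------------------------------
    t0 = time.perf_counter()
    insertions = detect_tandem_insertion(
        oset, min_unit=cfg.min_unit, max_unit=cfg.max_unit,
        max_mismatch_per_copy=cfg.max_mismatch)
    repeat_records = []
    for insertion in insertions:
        evidence = infer_ancestral_unit(oset, insertion)
        origin = None
        try:
            states = {sp: ("present" if sp in insertion.carrier_species
                           else "absent") for sp in oset.tree.tip_names}
            origin = map_origin_node(oset.tree, states,
                                     derived_state="present",
                                     ancestral_state="absent")
        except ValueError:
            pass
        if oset.cds and insertion.carrier_species:
            start, end = insertion.insertion_column_span
            noncarriers = [r.species for r in oset.protein_alignment.records
                           if r.species not in insertion.carrier_species
                           and r.species in oset.cds]
            sp = noncarriers[0] if noncarriers else insertion.carrier_species[0]
            if evidence.ancestral_unit:
                # seed segment: ancestral element + the residues that follow
                # it in the pre-expansion (non-carrier) sequence
                m = evidence.ancestral_unit_length
                stop_col = min(end + 3, oset.protein_alignment.n_cols)
                region = segment_cds(oset, sp, start - m, stop_col)
                seq, length = find_flanking_direct_repeats(region)
                evidence.flank_repeat_seq = seq
                evidence.flank_repeat_len_bp = length
                elem_cds = segment_cds(oset, sp, start - m, start - 1)
                pairs, structure, capable = nussinov_hairpin(elem_cds)
                evidence.hairpin_pairs = pairs
                evidence.hairpin_capable = capable
                evidence.hairpin_structure = structure
        repeat_records.append(slippage_report(insertion, evidence, origin))
    (out / "repeats.json").write_text(
        json.dumps(repeat_records, indent=2, sort_keys=True))
    report["repeats"] = [
        {"unit_length_aa": r["insertion"]["unit_length_aa"],
         "copies": r["insertion"]["copies"],
         "flank_repeat": r["evidence"]["flank_repeat_seq"],
         "flank_repeat_len_bp": r["evidence"]["flank_repeat_len_bp"],
         "hairpin_capable": r["evidence"]["hairpin_capable"],
         "ancestral_unit_length": r["evidence"]["ancestral_unit_length"],
         "origin_node": r["origin_node"]}
        for r in repeat_records]
    _log(f"[repeats] {len(insertions)} insertion span(s) "
         f"({time.perf_counter() - t0:.2f}s)")

    # --- promoters ------------------------------------------------------
    t0 = time.perf_counter()
    promoter_report = {}
    bed_lines = []
    for pid, seq in promoters.items():
        hits = scan_motif(seq, MEM1_B_CORE)
        promoter_report[pid] = {
            "n_core_hits": len(hits),
            "hit_offsets": [h.offset for h in hits],
            "submodule_present": submodule_present(seq, MEM1_B_CORE),
        }
        for h in hits:
            i = len(seq) + h.offset
            bed_lines.append(f"{pid}\t{i}\t{i + len(MEM1_B_CORE)}\t"
                             f"{h.motif_id}\t{h.mismatches}\t+\t{h.offset}")
    (out / "promoter_hits.bed").write_text(
        "\n".join(bed_lines) + ("\n" if bed_lines else ""))
    report["promoters"] = promoter_report
    _log(f"[promoters] {len(promoters)} promoter(s) "
         f"({time.perf_counter() - t0:.2f}s)")

    # --- expression (demo simulation) -----------------------------------
    if cfg.run_expression:
        t0 = time.perf_counter()
        from .synthetic_data import (SimConfig, simulate_expression,
                                     simulate_light_course)
        sim = SimConfig(seed=cfg.seed)
        matrix, _ = simulate_expression(sim)
        switch = recruitment_switch(matrix, "PPT1", "PPT2")
        series, _ = simulate_light_course(sim)
        light = stepwise_light_test(series)
        light.to_csv(out / "light_response.tsv", sep="\t", index=False)
        report["expression"] = {
            "switch": switch["switch"],
            "recruited_gene": switch["recruited_gene"],
            "leaf_switch": switch["leaf_switch"],
            "mc_switch": switch["mc_switch"],
            "light_stars": list(light["stars"]),
        }
        _log(f"[expression] switch={switch['switch']} "
             f"({time.perf_counter() - t0:.2f}s)")

    # --- selection (optional; heavier) ----------------------------------
    if cfg.run_selection:
        t0 = time.perf_counter()
        from .selection_test import (BranchSiteParams, selection_scan,
                                     simulate_codon_alignment)
        import numpy as np
        truth = BranchSiteParams(kappa=2.0, omega0=0.2, omega2=1.0,
                                 p0=0.6, p1=0.3)
        fg = {"N7"} | oset.tree.tips_under("N7")
        ca = simulate_codon_alignment(
            oset.tree, fg, truth, 120, np.random.default_rng(cfg.seed))
        table = selection_scan({"demo_gene": ca})
        table.to_csv(out / "selection.tsv", sep="\t", index=False)
        report["selection"] = {
            "genes": list(table["gene"]),
            "p_bh": [float(x) for x in table["p_bh"]],
        }
        _log(f"[selection] done ({time.perf_counter() - t0:.2f}s)")

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    return report
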