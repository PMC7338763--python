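# c4recruit

Comparative signatures of gene recruitment into C4 photosynthesis.

C4 plants concentrate CO2 around Rubisco by dividing carbon fixation
between mesophyll (MC) and bundle sheath (BSC) cells. The genes that run
this shuttle were not invented de novo — they are ancestral housekeeping
genes that were *recruited*: re-expressed in new tissues and cell types,
re-wired with new promoter elements, and modified in their coding
sequences. `c4recruit` implements, as one tested pipeline, the comparative
analyses used to document such a recruitment for a paralog pair (the
phospho*enol*pyruvate/phosphate translocators PPT1/PPT2 of *Flaveria*):

- **Consistent amino-acid modifications** — alignment columns fixed for
  one residue in all C3 species and a different residue in all C4
  species, with the origin of each change mapped onto the species tree by
  Fitch small parsimony.
- **Tandem-repeat insertions and slipped-strand mispairing** — detection
  of lineage-specific insertions as (unit length × copies) expansions,
  the ancestral single element that seeded them, direct repeats flanking
  the seed's coding DNA, and Nussinov hairpin capacity of the template.
- **Promoter cis-modules** — IUPAC motif scanning with start-codon-
  relative coordinates (the built-in library ships the MEM1 B submodule
  core 15-mer), global promoter identity, and conserved blocks split by
  insertions.
- **Expression shifts** — TPM/FPKM normalization, qPCR ΔCt
  quantification, per-interval Welch tests of light-induction series with
  the conventional star bins, and tissue/cell-type dominance-switch
  calls.
- **Branch-site positive selection** — a Goldman–Yang-style codon model
  with uniform 1/61 frequencies, the four-class branch-site mixture
  (foreground ω2 ≥ 1), χ²(1) likelihood-ratio test and
  Benjamini–Hochberg correction across genes.

A seeded synthetic-data module generates every input the pipeline
consumes, together with truth tables, so each stage is testable end to
end without external downloads. See `docs/methods.md` for the models,
defaults and limitations.

## Worked example

The bundled demonstration rebuilds the example reconstructions (a
16-taxon two-clade ortholog set carrying the clade-A insertion, and a
promoter carrying the MEM1 B submodule) and runs every stage:

```sh
c4recruit run-all --seed 0 --outdir demo_out
```

The report (`demo_out/report.json`) contains, among other fields:

```json
"repeats": [{
    "unit_length_aa": 13,
    "copies": {"Faus": 4, "Fbid": 4, "Fkoc": 5, "Fpal": 4, "Ftri": 4, "Fvag": 5},
    "ancestral_unit_length": 12,
    "flank_repeat": "GCGGCG",
    "flank_repeat_len_bp": 6,
    "hairpin_capable": true,
    "origin_node": "N7"
}],
"promoters": {"PPT1A_C4_promoter": {
    "n_core_hits": 2, "hit_offsets": [-2783, -2754], "submodule_present": true}},
"expression": {"switch": true, "recruited_gene": "PPT1", ...}
```

Reading: the C4/C4-like carriers share an insertion of four or five
tandem copies of a 13-amino-acid unit (52 residues in the 4-copy form)
whose origin maps to the stem node "N7" of the clade-A C4-like/C4 group;
a 12-residue element present in *all* species sits immediately upstream —
the likely expansion seed — and its coding DNA is flanked head and tail
by the 6-bp direct repeat `GCGGCG` and can fold into a hairpin, the
classic substrate of slipped-strand mispairing. The promoter carries two
copies of the 15-mer MEM1 B core at −2783 and −2754 bp upstream of the
start codon, and the expression matrix shows the recruitment switch: the
paralog that is minor in C3 leaves is dominant in C4 leaves and mesophyll
cells.

Individual stages are exposed as subcommands (`simulate`,
`consistent-mods`, `repeats`, `promoters`, `expression`, `selection`) and
as plain library functions.

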