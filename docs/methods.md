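# Methods

`c4recruit` implements the comparative analyses used to characterize how a
pre-existing gene is recruited into C4 photosynthesis, using the
phospho*enol*pyruvate/phosphate translocator paralog pair (PPT1/PPT2) of
*Flaveria* as the motivating system. The pipeline covers five signatures of
recruitment: fixed C3-vs-C4 protein differences and their phylogenetic
origins, a lineage-specific tandem-repeat insertion with slipped-strand
mispairing evidence, a promoter *cis*-module (MEM1 B submodule), expression
dominance switches between tissues and cell types, and a branch-site codon
model test of positive selection.

## Sequence model and conventions

Alignment columns are 1-based. Promoter coordinates are 1-based negative
offsets from the start codon (−1 = the base immediately upstream of the A of
ATG); the internal representation is 0-based half-open with a round-trip
tested converter. The only gap character is `-`; the `.` dialect is rejected
with an explicit error. Photosynthetic-type labels (`C3`, `C3-C4-I`,
`C3-C4-II`, `C4-like`, `C4`) ride on FASTA headers (`id|species|ptype`)
and/or a sidecar TSV; the sidecar wins on conflict because headers are
routinely mangled by alignment tools.

Global identity uses Needleman–Wunsch with match +1, mismatch 0, linear gap
−1 and deterministic traceback (diagonal > up > left). Identity is matched
columns divided by alignment length. The scoring is configurable because
published percent-identity figures rarely state their gap model; the default
is recorded in all outputs that report identities.

## Consistent modifications

A *consistent amino-acid modification* is an alignment column fixed for one
state across every C3 species and fixed for a different state across every
C4 species. Intermediate types (C3–C4, C4-like) never veto consistency;
they only inform origin mapping. Gap handling: the gap is a 21st character
state; columns that are gap in every grouped species are skipped; columns
forming a group-specific insertion (all-gap in one group, all-residue in the
other) are excluded from point-modification counts and routed to the repeat
detector, since a multi-residue insertion is one event, not one event per
column. Whether C4-like species join the C4 group is a flag
(`include_c4_like`, default off); note that with the default 16-taxon tree
one C4-like lineage sits in the clade lacking true C4 species, so enabling
the flag changes what can be consistent — the flag state is echoed in every
output header.

Origins are mapped with Fitch small parsimony on the rooted species tree.
The reported origin is the root-most node assigned the derived state whose
parent is not, under a minimal-change labeling in which root-level ambiguity
is resolved toward the ancestral (C3) state — this makes a tip-restricted
state map to the pendant branch rather than the root. With homoplasy the
origin covering the most derived tips is reported (ties broken root-most in
preorder). The Fitch score is validated against complete enumeration of
internal labelings on 6-tip trees. The union rule at multifurcating nodes
is the standard generalization; exactness is guaranteed for binary trees,
which is what the pipeline uses.

## Tandem repeats and slipped-strand mispairing

Repeat detection is alignment-anchored rather than de novo: an insertion is
a maximal run of columns occupied by a proper subset of species and gapped
in all others. Within each carrier's inserted segment, unit lengths from
`min_unit` (3) to `max_unit` (50) and all phases are searched exhaustively;
each candidate copy must sit within `max_mismatch_per_copy` (default 2) of
the positionwise-majority consensus. The winning unit maximizes residues
covered across carriers, with ties resolved toward the smaller unit — so a
duplicated 2×u decomposition never beats the u-periodic one. Spans shorter
than two minimal units are reported as non-repetitive insertions.

Slippage evidence has three parts. (1) The *ancestral element*: the longest
block of columns immediately N-terminal of the span that is fixed in all
species and equals a suffix of the consensus unit; its length relative to
the unit is reported (the motivating case is an element one residue shorter
than the unit — the expansion seed). (2) The *flanking direct repeat*: the
longest DNA word that is both a prefix and a suffix of the seed segment's
CDS (the element plus the residues that follow it in a non-carrier), capped
at half the region so head and tail cannot overlap. (3) *Hairpin capacity*
of the element's coding DNA, scored by the Nussinov maximum base-pairing
dynamic program with a minimum loop of 3 and G·T wobble pairs allowed (the
DNA is a transcript-strand proxy; wobble is switchable). "Hairpin-capable"
means the optimum reaches ceil(length/6) pairs — a structural-capacity
call, not a thermodynamic prediction; no nearest-neighbor energy model is
implied, and the threshold is an explicit artifact-level choice.

## Promoter modules

Motif scanning is exact-window IUPAC matching with an allowed substitution
count, on the coding strand by default (the motivating mesophyll-expression
module is reported on the coding strand; reverse-strand scanning is a
flag). The built-in library ships the MEM1 B submodule core 15-mer
(AAAACAAACAAAAAC); "submodule present" requires at least two core copies
starting within a 60 bp window, generalizing the observed
two-copies-in-44-bp geometry. No background model or enrichment statistic
is computed — presence, counts and positions only.

Conserved-block comparison chains exact 12-mer seeds on a common diagonal
(gap tolerance = window), keeps chains at least `window` (50) bp long with
at least `min_identity` (70) percent ungapped identity, and enforces
non-overlap within each promoter (longest block first). Detection is
seed-limited: a diverged region containing no exact 12-mer cannot be
reported. This is intentional — the use case is finding near-identical
promoter blocks split by insertions, not sensitive local alignment.

## Expression statistics

TPM and FPKM use the standard formulas; TPM columns sum to 1e6 by
construction and the two units are never merged silently. qPCR relative
abundance is 2^−(Ct_target − Ct_reference) against a reference gene
(ACTIN7 role in the motivating study).

Light-response series (default grid 0, 0.5, 2, 4 h) are tested per
consecutive interval with Welch's unequal-variance two-sample t-test on raw
relative abundances (two-sided, unpaired; a log option exists). The
published variant of "t-test" is not stated anywhere we could anchor to, so
the defaults are the least-assuming choice and are recorded in the output.
Star bins: `*` for 0.01 ≤ p < 0.05, `**` for 0.001 ≤ p < 0.01, `***` for
p < 0.001; a marginal band (0.05 ≤ p < 0.10) is reported separately because
the motivating analysis treats P = 0.075 as marginal. Zero variance on both
sides yields p = 1 for equal means and p = 0 otherwise, by documented
convention. No multiplicity correction is applied across intervals.

Dominance is log2 of the ratio of stratum means. A *recruitment switch* is
flagged when the paralog dominant in C4 leaf (and, when cell-resolved data
exist, in C4 mesophyll) differs from the paralog dominant in the same
stratum of C3 species.

## Branch-site selection test

The codon model is Goldman–Yang-style over the 61 sense codons with
equilibrium frequencies fixed uniform at 1/61 (so the generator is
symmetric), zero rate for multi-nucleotide changes, ×κ for transitions and
×ω for nonsynonymous changes. The branch-site mixture has four site
classes with (background, foreground) omegas (ω0,ω0), (1,1), (ω0,ω2),
(1,ω2) and proportions p0, p1, (1−p0−p1)·p0/(p0+p1),
(1−p0−p1)·p1/(p0+p1). All classes share one rate scale chosen so a unit of
branch length is one expected substitution per codon averaged over classes
(weighted by the background omegas): sites in the ω2 class therefore
genuinely evolve faster, which together with the dN/dS shift carries the
detectable signal. Transition matrices come from one symmetric
eigendecomposition per distinct omega (exactness against `expm` is tested),
and likelihoods from Felsenstein pruning over unique site patterns with
per-node rescaling.

Branch lengths are taken from the input tree up to a single global rate
scale estimated under the null and reused in the alternative; trees are
pipeline inputs here, and freeing 2n−2 lengths would dominate the fit cost
for little benefit at these problem sizes. Optimization is bounded
L-BFGS-B: the null (ω2 = 1) starts from a fixed documented grid (up to 3
starts); the alternative starts from the null optimum (making
lnL_alt ≥ lnL_null hold by construction) plus perturbed starts with ω2 at
3 and 8. Non-convergence is flagged on the result, never silent. The LRT
statistic 2ΔlnL (clipped at 0) is referred to χ²(1), and p-values are
Benjamini–Hochberg adjusted across genes at threshold 0.05.

Because the null pins ω2 at a boundary, the χ²(1) reference is
conservative; the calibration simulations below quantify the actual size.

## Synthetic data: what it emulates and what it does not

Every generator is deterministic under a fixed seed and emits a truth table
consumed by the recovery tests. The default species set is a stylized
16-taxon two-clade *Flaveria*-like tree whose clade-A C4-like/C4 stem is
labeled N7; branch lengths give root-to-tip depths around 0.1
substitutions/site, the shallow intrageneric regime where fixed differences
are rare and drift seldom erases a planted modification.

Protein evolution is Poisson substitution with a uniform kernel over the
20 amino acids; the consistency classifier is alphabet-agnostic, so an
empirical exchangeability matrix would add realism without changing what
recovery tests measure. Indels beyond the single configured insertion,
rate heterogeneity across sites, and alignment error are not simulated —
passing recovery tests therefore demonstrate correctness of the detectors,
not robustness to misalignment. CDS are generated by a fixed
lexicographic-first codon backmap, with exact DNA pinned where the
slippage analysis needs specific nucleotides (flank repeats, hairpin
unit). Expression values are log-normal around stratum means with a 4×
dominance effect and log-sd 0.3 (three replicates), matching the size of
shift the qualitative published pattern implies; light courses are
multiplicative log-normal noise (sd 0.15) around per-interval fold
changes on the 0/0.5/2/4 h grid.

For the selection test's calibration and power simulations the spec-level
quantities are 8 taxa, 300 codons (null) and 500 codons (ω2 = 5), with
foreground a two-tip clade and its stem. Branch lengths use the depths
standard in branch-site power studies (tips 0.15, internals 0.08, total
tree length ≈ 1.7, foreground ≈ 0.38 expected substitutions per codon):
at very shallow intrageneric depths the expected log-likelihood difference
between ω2 = 5 and ω2 = 1 is below one unit and no method has power, so a
power analysis there would be uninformative. Null calibration uses 200
replicates with two optimizer starts per fit; the power run uses 15
replicates. These problem sizes keep the full calibration suite in the
ten-minute range on one core.

## Known limitations

- The repeat detector assumes the aligner placed the lineage-specific
  insertion in a contiguous gap block; badly fragmented alignments will
  split spans.
- Fitch origin mapping reports a single primary origin; extensive
  homoplasy is summarized, not enumerated.
- The branch-site implementation fixes codon frequencies at 1/61 by
  design (matching the motivating analysis); other frequency models, site
  grids (NSsites ≠ 2), and Bayes empirical Bayes site identification are
  out of scope.
- Conserved-block detection is seed-limited and ungapped within blocks;
  it is not a substitute for local alignment.
- qPCR quantification assumes perfect amplification efficiency (exact
  doubling per cycle).
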