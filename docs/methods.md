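# Methods

This note documents the models and procedures implemented in `tastemine`,
the defaults and why they were chosen, what the synthetic data does and
does not emulate, and the numerical choices that affect results.

## Translated homology search

Protein queries are compared against all six reading frames of each
contig. Exact amino-acid word seeds (default word size 4) are located via
a per-frame hash index and extended without gaps in both directions under
BLOSUM62 with an X-drop rule (drop 18). Hits are reported in
forward-strand, 0-based half-open genomic coordinates.

The classical protocol for this kind of mining uses TBLASTN at an e-value
of 1e-10. An e-value requires the external tool's extreme-value
statistics; we instead expose a raw-score floor (`score_threshold`,
default 60) calibrated so that genuine receptor matches (hundreds of bits
even at 10–20% protein divergence) always pass while chance 4-mer seeds
in random sequence essentially never extend that far (measured: zero
false hits in 20 kb of random sequence per 300-residue scrambled query;
zero false loci in ~200 kb synthetic genomes). The e-value is retained
only as config metadata. This makes the search deterministic and free of
external binaries; the pre-installed `tblastn` is used in the test suite
as an independent oracle on a small fixture, never as the implementation.

Filtering and merging follow the mining protocol:

* hits spanning < 100 nt of genome are discarded (`min_hit_len`, strict
  `<`: a 100 nt hit is kept);
* hits on the same contig and strand whose intervals overlap are unioned
  transitively into candidate loci (half-open semantics: abutting
  intervals do not merge). Hits in *different* reading frames separated by
  at most 50 nt are also merged — a frameshifted pseudogene presents as
  split-frame hits and must become a single locus to be classifiable;
* merged loci are extended 500 nt in both directions (`flank`), clipped
  to the contig.

## Gene models and classification

Each extended locus is aligned to its best-scoring query with a local,
frame-aware dynamic program over (nucleotide position × guide residue):
the main move consumes one codon per guide residue (BLOSUM62-scored,
premature stops are alignable because BLOSUM62 defines `*` columns);
1- and 2-nt moves at a frameshift penalty (−14) cross ORF-disrupting
indels; a 3-nt non-consuming move (−10) crosses in-frame deletions. Gap
costs are linear: the only indels in scope are the 1–2 nt disruptions
themselves, which have dedicated transitions, so affine bookkeeping would
add states without discriminative power. Runs of frameshift moves are
coalesced into one event and reported only when the net shift is not a
multiple of 3; matched stop codons before the alignment end are reported
as premature stops with their codon index.

From the alignment the maximal ORF is extracted: the start codon is taken
at the guide's first aligned residue (scanning upstream in frame, past no
stop, when the alignment starts inside the gene), and the coding region
runs to the next in-frame stop. Classification:

| category | rule |
| --- | --- |
| INTACT | > 270 aa, start + stop present, no disruptions, ≥ 7 TM segments |
| PARTIAL | start or stop missing *and* the truncation coincides with a contig end |
| PSEUDO | any disruption; or a complete ORF with < 7 TM segments; or start/stop lost away from any contig edge |
| SHORT | complete clean ORF ≤ 270 aa (reported separately, not counted intact) |

The 270 aa boundary is strict (a 270 aa ORF is SHORT). Pseudogene
evidence outranks truncation: a contig-edge fragment carrying a
frameshift is PSEUDO, because a disruption is positive evidence of
nonfunctionality while truncation is only missing evidence. The TM screen
applies to complete ORFs only — fragments cannot be fairly screened.
Truncation by assembly-gap N-runs is treated like a contig edge only in
the sense that loci in mostly-N contigs are skipped at search time; the
synthetic genomes do not model internal N-runs.

Transmembrane segments are counted by Kyte–Doolittle sliding-window
hydropathy (window 19, threshold 1.6, runs of above-threshold windows
separated by ≥ 3 below-threshold windows). These are the textbook
hydropathy-plot settings; the count is validated against an independent
per-window loop in the tests. A dedicated HMM topology predictor would be
stricter, but the screen's role here is to reject non-GPCR ORFs, not to
annotate topology.

Partial fragments of one species are disambiguated by their guide-aligned
intervals: fragments covering overlapping guide regions must be different
gene copies; fragments covering complementary regions are fused into one
inferred locus (greedy chaining in guide-coordinate order). Reciprocal
verification scores each protein against a labelled reference panel
(target families plus decoy GPCR families such as V1R/V2R) and rejects
models whose best panel hit is a decoy. Gene names follow the
four-letter convention `Xxxx_FamilyN` (genus[:2] + epithet[:2],
numbered in genomic order).

## Synteny absence calls

A target family is ABSENT when both flanking markers lie on one contig
within `max_span` (default 1 Mb) with no target hit between them;
PRESENT/PSEUDOGENE when models exist; UNDETERMINED otherwise (markers
split across contigs, missing, or too far apart). The 1 Mb span is a
conservative default — conserved flanking in well-assembled regions is
typically much tighter. Because the published wording distinguishes
confident absence (Tas1r1) from "perhaps lost" (Tas1r2/Tas1r3), a
permissive mode reserves ABSENT for directly adjacent markers (< 10 kb)
and returns UNDETERMINED otherwise. Marker positions are consumed as
annotations (GFF3/TSV); finding the markers themselves is out of scope.

## Reconciliation and trajectories

Gene trees (leaf labels `Species_gene`) are embedded in the rooted binary
species tree by the LCA mapping M. A gene node is a duplication iff
`M(node) == M(child)` for one of its children; per gene edge (u, v) the
loss count is `depth(M(v)) − depth(M(u)) − 1` after a speciation and
`depth(M(v)) − depth(M(u))` after a duplication, each loss charged to the
sibling species branch not taken on the path. The LCA mapping minimises
duplications and losses simultaneously; the implementation is verified
against an exhaustive search over all valid mappings (exact agreement on
hundreds of random tree pairs). Unrooted input trees can be rooted on the
branch minimising D+L (ties broken by D, then canonical branch order).
Non-binary trees are rejected with a clear error rather than silently
resolved, and no bootstrap-threshold rearrangement of weak edges is
attempted — the input topology is reconciled as given.

Per-branch gains are duplications charged to the branch above the
duplication node's mapping; losses as above. Ancestral counts propagate
from the root (root lineages = 1 + root-mapped duplications per family)
so that `child = parent + gains − losses` holds on every branch; a
contradiction with observed leaf counts raises an error naming the
branch. Note the standard LCA limitation: events above the gene root
(families never present in part of the species tree) are invisible, so
observed-count checking is only meaningful for families spanning the
root.

A neighbor-joining fallback (dendropy's implementation, taxa sorted for
deterministic ties) builds gene trees from distance tables when no
externally inferred tree is supplied. Likelihood tree inference,
alignment trimming and bootstrap support are out of scope.

## Selection

`count_sites` implements NG86 site counting: per codon position, the
fraction of the three single-nucleotide changes that is synonymous,
excluding changes to stop codons from the denominator and renormalising
each position to weight 1, so S + N = 3 per codon. Observed differences
average uniformly over all shortest mutational pathways between the two
codons, excluding pathways through stops (if every pathway is blocked,
all changes count as nonsynonymous). Proportions pN = Nd/N̄, pS = Sd/S̄
use site counts averaged over the two sequences and are Jukes–Cantor
corrected; ω = dN/dS is flagged undefined when dS = 0 or a proportion
reaches the 3/4 saturation bound. Gapped or ambiguous codons are dropped
pairwise. Agreement with an independent NG86 implementation (Biopython's
`cal_dn_ds`) is to within a few percent; the residual difference is the
stop-adjacent site convention. One counting subtlety: codon pairs whose
every shortest pathway crosses a nonsynonymous intermediate (e.g. the two
serine codon groups) contribute fractional Nd even between purely
synonymously evolved sequences, so ω estimates at very small true ω are
slightly positive rather than exactly 0.

`mean_family_omega` averages the defined pairwise ω values and reports
the undefined count. On simulated alignments the estimator recovers
ω = 0.2 within ±0.05 (500 codons, 9 taxa) and preserves the rank order of
ω ∈ {0.2, 1, 2}; at ω = 2 it underestimates (≈1.6) because pathway
counting and the JC correction saturate — rank, not magnitude, is the
reliable signal above 1.

The site-wise scan classifies each codon column by comparing its observed
nonsynonymous/synonymous change counts with the neutral expectation
(nonsynonymous site fraction of the column's codons) via binomial tail
probabilities; score = 1 − tail, threshold 0.9. Changes are counted
against the column consensus codon — a star-tree parsimony in which each
mutation is counted roughly once. Pooling over all sequence pairs would
count each mutation up to n−1 times and destroy the binomial calibration.
Detection power is intrinsically low per site because the neutral
expectation is already ~70% nonsynonymous: a 0.9 score needs on the order
of 20 observed changes in a column, i.e. dense alignments (tests use a
50-taxon star tree at branch length 0.6, where ≥ 6 of 10 planted ω = 5
sites are recovered with no false positives among ω = 0.1 background).
This scan is a qualitative stand-in for likelihood site models (M7/M8,
FUBAR); published per-site counts from those tools on real alignments are
not reproducible by counting methods, and no likelihood-ratio machinery
is implemented.

## Taste prediction

Umami ⇔ intact Tas1r1 ≥ 1 and intact Tas1r3 ≥ 1; sweet ⇔ intact
Tas1r2 ≥ 1 and intact Tas1r3 ≥ 1. Table entries like `2(1PS)` resolve to
intact = total − pseudo. The packaged 14-species amphibian table
reproduces all published umami/sweet calls; its cohort tallies are 7
species without either modality, 2 without sweet only, intact totals
16/9/9 for Tas1r1/2/3, and 17 pseudogene-or-absent Tas1r slots (3
pseudogene annotations + 14 empty species×family slots).

## Synthetic data: what it emulates and what it does not

Planted intact genes are built from 7-TM-shaped template proteins —
seven hydrophobic blocks (19–23 aa over {I,L,V,F,A}) separated by
strongly hydrophilic loops — so the TM screen passes by construction and
the simulator stays independent of any particular topology predictor.
Protein lengths are drawn uniformly so coding sequences span 816–1272 nt,
the published length range of intact bitter-receptor genes. Divergence
from the query panel is applied at the protein level
(hydrophobicity-class-preserving substitutions, Met1 fixed) and
back-translated with uniform codon choice, preserving ORF integrity;
10% divergence is the default mining benchmark. Pseudogenes carry 1–2
engineered disruptions (premature stop or 1–2 nt indel, never the start
codon, kept away from the termini); partials keep 45–70% of the ORF and
terminate exactly at a contig edge. Background sequence is i.i.d. at the
configured GC (default 0.42, a typical vertebrate value). Coordinates are
0-based half-open on the forward strand; GFF3 output converts to 1-based
inclusive.

Not emulated: introns (the multi-exon structure of real Tas1r genes is
out of scope; single-ORF input is assumed), repeats and segmental
duplications, assembly-gap N-runs, codon-usage bias, and realistic
pseudogene decay (many old real pseudogenes carry dozens of disruptions).
Perfect recovery on these genomes therefore demonstrates correctness of
the pipeline logic, not expected field performance on noisy assemblies —
real divergence between query panels and target genomes can exceed the
benchmarked 10%, and real loci can overlap tandemly.

Family histories evolve along a unit-time species tree: each gene lineage
independently duplicates (birth rate) or dies (death rate), events per
branch Poisson with uniform placement. Surviving lineages form the gene
tree; the full truth log is kept, with duplications flagged unobservable
when one of their copies left no descendants (LCA reconciliation can only
recover observable events; on loss-free histories recovery is exact and
branch-correct, which the tests assert). Codon alignments evolve each
site by a continuous-time codon process — transition/transversion ratio
kappa (default 2), nonsynonymous rates scaled by the site's ω, stop
codons unreachable, rates normalised per site so branch lengths are
expected substitutions per codon under uniform codon frequencies.

## Determinism and problem sizes

All randomness flows through seeded numpy generators; equal seeds give
byte-identical genomes, histories, alignments and pipeline outputs (the
test suite diffs whole output directories). Default validation sizes —
30-gene genomes of ~35 × 6 kb contigs, 200 oracle tree pairs (gene ≤ 6
leaves, species ≤ 4, where exhaustive search is exact and fast), 50
replicate families, 400–500-codon alignments on 9 taxa — were chosen so
the statistical assertions (recovery rates, ±0.05 ω tolerance from pilot
replicate spread) are stable across seeds while the whole suite stays
interactive; the generators scale to larger settings through `SimSpec`
and the simulation functions' parameters.
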