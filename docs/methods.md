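# Methods

This note documents the models, conventions and numerical choices behind
`plastmarker`, and what the synthetic validation does and does not show.

## Coordinates and data model

All internal coordinates are 0-based, half-open, on the forward strand of
the stored orientation. Conversion to 1-based conventions happens only at
I/O boundaries (GenBank, GFF3 and VCF 1-based; BED 0-based). `N` bases are
accepted in input but treated as missing by every variant/diversity
computation. Gene features carry one or more exonic parts (multi-part
features encode introns and trans-spliced genes); genes duplicated by the
inverted repeat appear as two features sharing a name.

## Quadripartite structure

The detector finds the longest pair of *exact* inverted repeats on the
circle: 20-mer seed matches between the doubled sequence and its reverse
complement are grouped by anti-diagonal, extended maximally, and the
longest disjoint pair kept. The longer single-copy gap is labelled LSC,
the shorter SSC; coordinates are rotated so LSC starts at 0 with order
LSC–IRb–SSC–IRa, and the rotation offset is kept for mapping back.
Exactness is a modelling decision, not a shortcut: in the target system the
two IR copies are identical (concerted evolution), and at ~22.8 kb the IR
pair is unique, so equal-length competing candidates or equal-length
single-copy segments are reported as errors rather than silently resolved.
`min_ir_len` defaults to 1,000 bp to exclude short dispersed repeats.
Seed k-mers occurring more than 64 times are masked (low-complexity
control); the true IR always contains abundant unique seeds. The SSC is
reported in the orientation found and never flipped — plastomes exist as
two SSC-orientation isomers, and fabricating a strand would be arbitrary.

Junction context reports, for each of the four boundaries, the nearest
annotated gene with a signed distance: ≥ 0 for a gene lying entirely on one
side (0 when it abuts the junction), negative when the gene spans the
junction, by the number of bases it reaches across.

## Collinear alignment and variant calling

Genomes of one species complex are collinear (no rearrangements), so a
center-star multiple alignment is exact in practice: every genome is
aligned to the reference by banded global alignment (match +1, mismatch −2,
gap open −5, gap extend −1; a gap of length L costs 5 + L; band half-width
200 columns around the corner-to-corner diagonal; numba-compiled kernel),
and the pairwise alignments are merged on reference coordinates. Shared
insertions occupy shared columns. Inputs whose lengths differ by ≥ 1 %
raise a collinearity error with the advice to supply an external alignment,
which is accepted verbatim.

Variant calling reads alignment columns: one SNP per polymorphic
substitution column; maximal runs of gap columns in one sample merge into a
single InDel event, represented VCF-style with an anchor base and
normalized by right-trim/left-extend (left alignment), so a gap placed
anywhere within a homopolymer yields the identical record. Sites containing
N are excluded. Records are multi-allelic where samples disagree.

A variant is *diagnostic* when every group is fixed for one allele and at
least two groups differ. The induced partition of groups determines the
category: `three-way` (≥ 3 cells), `two-vs-rest`, `one-vs-rest`. Fixation
is required exactly (no frequency threshold), matching the species-specific
marker use case.

Per-class sequence identity is the mean over sequence pairs of the percent
of identical columns within a class (tRNA, rRNA, exon, intron, intergenic);
a gap in one row counts as a difference, a gap in both rows as identity
(neither sequence has the base). Insertion columns inherit the class of the
preceding reference position.

## Nucleotide diversity

Pi is the average over sequence pairs of per-site differences. Windows
(default 500 bp, step 250 bp) slide over alignment coordinates; within a
window, columns containing a gap or N in any row are removed before
counting (complete deletion, the default site handling of the standard
desktop tool for this analysis); a pairwise-deletion variant is available
behind a flag. Windows whose Pi cannot be computed (no comparable site) are
NaN and excluded from summaries. A trailing window is anchored at the
alignment end so the track covers the full length.

Per-region summaries assign a window to LSC/SSC/IR only when the window is
*fully contained* in the region; windows straddling a junction are excluded
from region averages. (Assignment by window midpoint would leak single-copy
variation into the IR average through straddling windows; with containment,
data whose IRs are identical across samples yield IR Pi exactly 0, which is
the biologically meaningful statement.) Per-group Pi is computed over the
group's samples only, on the full alignment. Hotspots are windows with
Pi above a threshold (default 0.01), labelled by the locus at their
midpoint.

## In-silico PCR and digestion

Primer binding requires an exact 3'-terminal base and at most 2 total
mismatches (a designed dCAPS mismatch primer must still amplify). On
circular templates the search wraps the origin. The product is the smallest
correctly oriented amplicon ≤ 5,000 bp, with primer bases incorporated into
the product sequence; two distinct minimal products raise an ambiguity
error, and a missing binding site is a no-amplification result, not an
exception.

Digestion cuts at every recognition-site occurrence, at the enzyme's
top-strand cut offset (TaqI = T^CGA, XbaI = T^CTAGA; both palindromic; for
non-palindromic sites the opposite strand is scanned with the mirrored
offset). Fragment sizes are measured between top-strand cut positions and
always sum to the product size. With an asymmetric cutter the fragment list
of a reverse-complemented product differs from the reversed list by the
overhang width; the mirror symmetry of the machinery is exact for
blunt-cutting enzymes (offset = site length / 2) and is tested there.

## Marker design

*InDel markers.* For each diagnostic InDel of at least the resolvability
threshold (10 bp, suited to 2–3 % agarose; the smallest difference used in
practice is ~15 bp), primers are placed in flanking sequence that carries
no variant in any sample, the forward primer scanning outward from the
event and the reverse primer chosen to give a 100–300 bp product. Expected
product sizes per group come from in-silico PCR on one representative per
group and must show ≥ 2 distinct sizes separated by the threshold.

*dCAPS markers.* For each enzyme, strand and placement of the recognition
site over a diagnostic biallelic SNP: the part of the site downstream of
the SNP must already match the template; the part upstream is written into
a primer whose 3' terminus sits one base before the SNP, with at most one
introduced mismatch and never at the 3' base; the SNP itself supplies the
site's remaining base for exactly one allele. Zero introduced mismatches is
the degenerate CAPS case and is flagged as such. The dCAPS primer is kept at
maximal configured length (the mismatch destabilizes annealing; long
primers are the norm for dCAPS), and composition rules — length 18–26 nt,
GC 30–70 %, Wallace-rule Tm 2(A+T)+4(G+C) in 50–68 °C, homopolymer ≤ 5 —
apply to conventional and opposing primers, whose placement is free. Every
candidate is verified by in-silico PCR and digestion on a representative
genome per allele; a design is emitted only when the recognition site
overlapping the SNP exists in exactly one allele's product and the largest
fragments of the two allele patterns differ by ≥ 10 bp.

*Validation* predicts band patterns for every sample and passes when the
pattern is constant within groups and distinct between at least two groups;
any amplification failure fails validation with the sample named.

## Phylogeny

Single-copy protein-coding genes present exactly once in every taxon are
spliced on the coding strand and concatenated. In a pipeline run, where
only the reference is annotated, gene columns are read directly off the
whole-genome alignment (sample insertions inside genes are dropped —
a few sites at most in this regime); for fully annotated inputs, genes are
aligned per gene by the same banded aligner and concatenated with recorded
partitions.

Trees are Saitou–Nei neighbor joining on p- or JC69 distances with pairwise
deletion of gap/N sites (JC69 is undefined at p ≥ 0.75 and errors, naming
the pair). Determinism is part of the contract: Q-matrix ties break on the
smallest pair index, negative branch lengths clamp to zero, and the
bootstrap resamples alignment columns through a seeded multinomial over
unique column patterns, so a fixed seed gives bit-identical newick output.
Support is the frequency of each bipartition among replicate trees, and the
tree is rooted on the outgroup by splitting its edge. NJ is used instead of
maximum likelihood deliberately: for genomes this similar the signal is a
set of shared substitutions, which distance methods recover exactly, and
the bootstrap machinery is the quantity under test.

## Synthetic complex generator

The generator emulates the statistical structure the analysis assumes,
with exact machine-readable truth:

- **Ancestor** — quadripartite genome (defaults LSC 83,000 / SSC 12,500 /
  IR 22,800 bp, the scale of the real assemblies) with a plastome-like gene
  layout (~80 genes including intron-bearing and junction genes: *rps19*
  fully inside IRb 35 bp from the LSC border, *ndhF* spanning IRb/SSC by
  29 bp), base composition ~38 % GC, IRa constructed as the exact reverse
  complement of IRb. The bases immediately flanking the IR boundaries are
  set so the maximal exact IR equals the constructed one, and are kept
  mutation-free, so structure detection recovers the configured lengths
  exactly in every sample.
- **Species tree** — branch SNP/InDel budgets chosen so per-species totals
  against the reference equal the observed counts for the six species:
  68/43 (spontaneum, including fixed 27 bp and 50 bp insertions), 20/12
  (robustum), 22/10 (sinense, barberi), 10/5 (officinarum), plus a distant
  outgroup. Mutations are placed uniformly in single-copy regions
  (transition:transversion 2:1, geometric InDel lengths with mean 3),
  outside forbidden zones: planted SSRs, conserved flanks (±200 bp) around
  planted diagnostic sites, and the IR boundary bases. The observed data
  show zero IR variation across samples, so by default no mutations land in
  the IRs; `allow_ir_mutations` enables IR SNPs, mirrored to the other copy
  (concerted evolution) unless `mirror_ir` is disabled for negative tests.
- **Planted features** — six SSRs (mono→tetra motifs) at named spacers;
  diagnostic SNPs at *trnG-trnM* (robustum A vs G), *rbcL-psaI*
  (sinense+barberi A vs G) and a three-allele site at *psbM-petN*;
  diagnostic insertions at *rpl33-rps18* (15 bp, spontaneum+outgroup),
  *trnR-rps14* (26 bp officinarum / 16 bp outgroup → three product sizes)
  and *rps16-trnQ* (29 bp outgroup). Planted SNPs receive a 5' context
  (`TGTAG`) that admits both TaqI and XbaI dCAPS designs with one
  introduced mismatch. Planted events are deducted from their branch
  budgets so per-species totals stay exact.
- **Truth** — every per-sample event in normalized reference coordinates,
  the planted SSRs and diagnostics, and the true tree, enabling exact
  recall/precision measurement.

Events are placed with reserved intervals (SNPs ≥ ~3 bp apart, InDels
≥ ~18 bp from anything) so that left-alignment cannot make two events
collide; recall/precision 1.0 is therefore the *expected* outcome when the
caller is correct, which is what the recovery tests assert over seeds 1–10.

`tiny_config` provides a ~24 kb configuration (segments, gene lengths and
budgets shrunk 4–8×) for scale-free tests; study-scale runs use the full
defaults. For topology recovery, `phylo_recovery_tree` keeps the same tree
shape with branch budgets at the observed *inter-genus* divergence scale
(~2 % on the deepest path, matching the minimum whole-plastome identity
across the wider panel): with only the intra-complex budgets (tens of
SNPs), internal branches fall below the bootstrap noise floor contributed
by the long outgroup branch — an information limit of the data, not of the
algorithm — whereas at divergence scale NJ recovers the planted topology
with ~100 % support.

What the synthetic validation does **not** show: performance on genomes
with rearrangements or IR expansion/contraction (out of scope by design),
realistic codon-structured evolution, sequencing/assembly error, or
mutation-rate heterogeneity along the genome (real hotspots arise from
rate variation; here hotspot structure exists only if planted). Product
sizes and band patterns are sequence-arithmetic predictions; no
thermodynamic primer screening is performed.

## Problem sizes used

The test suite exercises desk-scale genomes (~24 kb) for scale-free
properties and the full ~141 kb configuration for the recovery tests
(seeds 1–10) and the acceptance script, which runs the complete study-scale
pipeline (12 genomes, ~141 kb each) plus a divergence-scale phylogeny
simulation with a 1,000-replicate bootstrap.
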