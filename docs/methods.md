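# Methods

## The reconstruction problem

Two endonuclease-induced double-strand breaks (HO and I-SceI, each leaving
a 4-nt 3'-protruding single-stranded overhang) are rejoined in trans by
classical NHEJ, reconstituting a selectable reporter whose tolerant intron
spans the new junction. Each recovered translocant yields one Sanger-read
junction sequence. The package answers, for each junction: *what is the
most parsimonious repair event — trimming, annealing, templated or
untemplated synthesis — that produced this sequence from the two known
ends, and which mechanistic class does it belong to?*

All sequence handling is on the top strand, 5'→3' left-to-right, 0-based
half-open coordinates. The left end's overhang is on the top strand (its
full top strand is flank + overhang); the right end's overhang is on the
bottom strand, so its top strand is recessed and the overhang's top-strand
image (`reverse_complement(overhang)`) can appear in a repaired junction
only as newly synthesised, overhang-templated fill. This asymmetry is
forced by the geometry of two 3'-protruding ends facing each other.

## Explanation model

A candidate repair event ("explanation") is a triple
(`trim_left_prot`, `trim_right_rec`, `insertion_top`) satisfying the
reconstruction identity

    junction == left_top[:len - trim_left] + insertion + right_top[trim_right:]

with trims bounded by `max_deletion` and the insertion by
`max_insertion`. Enumeration over the (trim, trim) grid determines the
insertion, so the search is complete within bounds; raising the bounds
never removes a solution (a property the tests check).

On top of the string identity, each explanation is annotated
mechanistically:

* **Pairing.** While the right end's top strand is intact, its retained
  bottom-overhang bases lie opposite the left remnant's 3' tail; a
  maximal annealing run is scored base by base, tolerating one internal
  structural mismatch (a dangling terminal mismatch is not a pair). In
  this assay pair the intact ends pair perfectly at the 1- and 2-nt
  terminal registers, and after one-nucleotide trimming of each 3'
  terminus the 3-nt pairing carries exactly one T:G mismatch.
* **Mismatch-repair alleles.** A tolerated pairing mismatch is resolved
  later by mismatch repair, so the junction may legitimately carry either
  strand's letter at that position. Enumeration therefore also admits
  single-position deviations from the left parent whose letter equals the
  complement of the paired overhang base; the deviation is counted as one
  pairing mismatch, and its resolution side is recorded.
* **Microhomology.** `mh_len` is the longest run of junction bases
  attributable to both parents — either direct sequence identity that
  lets the breakpoint slide (the usual deletion-junction microhomology),
  or base pairing between retained overhang bases (strand-crossing
  annealing). The larger of the two is reported.
* **Templated insertions.** An insertion is *templated* when it equals,
  contiguously and junction-proximally, the top-strand image of the
  opposing retained bottom overhang. Net-new bottom-strand bases opposite
  a retained left overhang are always synthesis on that overhang, so the
  bottom flag records whether such fill exists.

## Parsimony ranking

Among all explanations the winner minimises, lexicographically:
total trimmed + inserted nucleotides; then maximal microhomology; then
fewest pairing mismatches; then templated over untemplated insertions;
then left-aligned placement of junction-ambiguous bases (minimal left
trim). Final lexicographic components on the raw fields make the order
total, so ranking is deterministic and byte-reproducible. The ranking is
a design choice of this package — junction studies assign events by
inspection — but it reproduces every worked interpretation of the assay
signatures, and the test suite checks it against an independently coded
argmin on a thousand random junctions.

## Repair-type taxonomy

The winning explanation is classified by a decision tree, with precedence
ordering clauses that an explanation may satisfy simultaneously
(preferring readings that preserve more end structure).

Partially complementary system (precedence I > III > IV > II):

* **Type I, gap-filling-mediated** — both overhangs fully retained, a
  perfect 1- or 2-nt terminal pairing, and the remaining gap filled by a
  templated insertion (the +CA / +AT signature at the 2-nt register).
* **Type III, direct ligation without gap-filling** — at most one
  nucleotide trimmed from each protruding strand, a ≥3-nt pairing with at
  most one mismatch, no insertion and no fill on either strand.
* **Type IV, end-bridging** — one protruding strand degraded (blunted),
  with net-new bases synthesised across the other, intact overhang used
  as template: either bottom-strand fill across the intact left overhang,
  or a top-strand insertion templated by the fully retained right
  overhang.
* **Type II, microhomology-mediated** — a ≥4-nt annealing between one
  overhang and sequence adjacent to the other end, with deletion beyond
  the overhang on at least one side.

Non-complementary system (precedence I > II > III): Type I is two-strand
gap-filling across intact overhangs; Type II uses ≥1 nt of microhomology
with fill on exactly one strand; Type III uses microhomology with no fill
at all. Junctions fitting no clause are reported as unclassifiable, never
dropped; co-optimal explanations mapping to different types are flagged
ambiguous and excluded from cohort percentages.

A known arithmetic wrinkle in the source description: 1-nt terminal
pairing leaves 3-nt gaps (+ACA/+TAT fill) while 2-nt pairing leaves 2-nt
gaps (+CA/+AT), although the original narrative quotes 2-nt gaps for
both. The classifier keys on intact overhangs plus templated fill at any
perfect register rather than a fixed gap size, so both registers are
Type I.

## Assay configurations

Overhang sequences are reconstructed from the canonical enzyme
geometries (I-SceI: recognition TAGGGATAACAGGGTAAT, 4-nt 3' overhang
ATAA; HO: Y/Z-junction cleavage CGCAACA^GTATAA, overhang AACA). The
left/right end combination then reproduces, with no free parameters, the
assay's diagnostic facts: the 1- and 2-nt perfect pairing registers, the
+CA/+AT templated fill, the single T:G mismatch of the 3-nt Type III
pairing, and the complete non-complementarity of the inverted-site
system. The intron context around the ends is available only as figure
images, so the shipped flanks are synthetic stand-ins (marked as such in
the config files) constructed to provide exactly one full annealing site
for each overhang inside the deletion window plus short suffix
microhomologies, so that every repair type of both systems is simulable
and uniquely decodable. Junctions from the real assay would need the
true flanks transcribed into the same config format.

`max_deletion` (25 nt per side, overhang included) reflects the selection
constraint that the junction-spanning intron must remain functional, and
the observation that recovered events never use more than ~5 nt of
microhomology; `max_insertion` (6 nt) generously bounds observed fills
(≤4 nt). Both are per-assay configuration.

## Simulator

`simulate_junction` executes a mechanism literally — choose a register or
annealing site, trim, fill templated gaps, ligate — and emits the
junction with its ground-truth explanation (self-checked against the
reconstruction identity on emit). Microhomology placements are sampled
among the precomputed annealing sites of the configured flanks; an assay
without a required site raises a configuration error rather than
fabricating sequence. Cohorts draw types i.i.d. from a per-strain
mixture; the shipped profiles are the published per-genotype counts
divided by n. `mmr_resolution_prob` (default 0.5, not quantified in the
source) sets the chance a Type III mismatch resolves to the left-end
allele.

Randomness is a single integer seed; junction *i* uses substream
`SeedSequence(entropy=seed, spawn_key=(i,))`, so cohort prefixes are
stable under cohort-size changes and independent of iteration order.

Plating experiments draw binomial survivor and translocant counts from a
plated cell number (survival default 0.3; the published survival is
plotted, not printed). What the simulator deliberately does **not**
model: sequencing/chromatogram noise, clonal duplicates among
translocants, real intron sequence composition, resection kinetics, or
any repair pathway outside the configured mechanisms. Passing round-trip
tests therefore demonstrate internal consistency of
generator + classifier under the stated mechanisms, not classifier
performance on arbitrary real reads.

## Cohort statistics

Frequencies are exact ratios of dilution-corrected colony counts
(survival = SGal/SC, translocation frequency = SGal-Leu/SC; the in-cis
assay substitutes 5-FOA-resistant counts). Replicates are summarised by
the median (standard deviation alongside). Fold changes report max/min
with direction, rounded to the nearest integer below 100 and to one
significant figure above (so 298 renders "300-fold"). Mann-Whitney
comparisons are two-sided, exact-permutation when the smaller group has
≤8 observations and no ties, tie-corrected normal approximation
otherwise. Repair-type distributions are compared with a Pearson
chi-square on the raw counts, no continuity correction,
df = (categories−1)(groups−1), with a warning when any expected count
falls below 5 — which is the case for most published rows. Notably, the
published significance annotation for the tel1Δ vs wild-type comparison
(p<0.005) is not recoverable from the printed counts with a standard 2×4
Pearson test (chi2 = 8.01, p = 0.046); the module reports its own
p-values and makes no attempt to match the annotation. Percentages in
all reports are rendered from counts (half-up integer rounding), never
stored independently.

## Karyotype arithmetic

Translocated chromosome sizes are left-fragment + right-fragment sums in
kb over a perfect matching of fragments, conserving total material.
Only the product sizes are published (596/811 kb and 1450/730 kb); the
shipped chromosome lengths and break offsets are a synthetic
reconstruction consistent with those sums and with a single shared break
position on the common chromosome.

## Numerical and degenerate-input conventions

Empty cohorts mark percentages as undefined rather than emitting 0/0;
blunt or 5'-overhang cut specifications are rejected; junctions missing
an anchor are rejected at parse time with a machine-readable reason;
duplicate FASTA ids and non-ACGT characters are errors. All outputs are
byte-stable for fixed (inputs, seed): reports carry a single version/seed
header line, JSON keys are sorted, and table ordering follows input
order.

## Problem sizes used by the acceptance script

Type-distribution cohorts use the published compositions and cohort
sizes verbatim. Frequency estimates use 10 simulated plating replicates
of 10^8 cells per genotype, giving sub-percent relative error at the
smallest published frequency (0.005×10⁻³) so that rounded fold
descriptors are stable across seeds. The classifier/oracle agreement is
measured on 1000 random junctions (alternating systems) and truth
recovery on 25 simulated junctions per type per system.
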