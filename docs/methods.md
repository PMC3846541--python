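# Methods

## The problem

Antigen-receptor diversity arises from V(D)J recombination: the RAG
recombinase cuts at recombination signal sequences (RSSs) — a conserved
heptamer (consensus `CACAGTG`) and nonamer (`ACAAAAACC`) separated by a
spacer of ~12 or ~23 nt — and joins gene segments by deletion or
inversion of the intervening DNA. Joining pairs one 12-spacer RSS with
one 23-spacer RSS (the 12/23 rule). The chromosome retains *coding
joints* (two trimmed coding ends, usually separated by untemplated
"N-region" nucleotides added by TdT) and, for inversions, also a
*signal joint* (two heptamers fused head-to-head, typically precise).
Erroneous recombinase activity produces lineage-inappropriate events,
V-to-V deletions through cryptic heptamers inside coding sequence, and
oncogenic reciprocal translocations.

`vdjcapture` models the capture-sequencing assay used to survey this
activity in genomic DNA: RSS-directed hybrid-capture enrichment,
paired-end sequencing, discordant-pair candidate discovery, and
split-read breakpoint refinement to single-base resolution, followed by
the full junction workup (joint type, N-region vs microhomology, 12/23
compliance, frame/productivity, event category, per-derivative loss
accounting for reciprocal translocations).

## Coordinate and junction conventions

All coordinates are 0-based half-open; human-readable reports print
1-based inclusive positions. An RSS with orientation `+` reads
heptamer→spacer→nonamer left-to-right on the plus strand; `-` means the
reverse complement does. Two RSSs are in deletional configuration when
the left is `+` and the right is `-` (heptamers facing); same
orientation means inversional configuration.

A junction is an ordered pair of sides plus an insert. The left side
`(chrom, pos, orient)` contributes the flank entering the seam (`+` =
reference `[.., pos)` forward; `-` = reverse complement of
`[pos, ..)`); the right side contributes the flank leaving it.
Junctions are **canonicalized** (lower-coordinate side first; flipping
reverse-complements the insert) and then **left-shifted**: insert bases
indistinguishable from a flank continuation are absorbed into that
flank, and with no insert remaining the seam slides through any
junctional microhomology to its leftmost equivalent position. Under
this convention a junction has either N > 0 and microhomology 0, or
N = 0 and microhomology ≥ 0, and "single-base resolution" is
well-defined. Simulator truth and detector output share this normal
form, so they are compared by equality. Bases attributable to either
flank are always microhomology, never N — reported N-region lengths are
therefore lower bounds in the rare case an untemplated base coincides
with the reference continuation (the generator resamples edge bases so
planted inserts survive decomposition intact; real data offers no such
guarantee).

## Synthetic loci

`build_synthetic_model` lays out each locus on its own chromosome:
margin, V array, D array, J array, margin, with uniform random
background sequence from a seeded generator (byte-identical output for
a fixed blueprint). Defaults: V coding 300 nt with a 3′ 23-spacer RSS;
D coding 24 nt with a 5′ 12-spacer and 3′ 23-spacer RSS; J coding 51 nt
with a 5′ 12-spacer RSS; 400–650 nt spacing; every canonical join (V-D,
D-J, V-J) is thereby 12/23-compliant. `invert_j` places J segments in
inverted orientation so V-to-J joining proceeds by inversion (the
IGK-like situation). Options plant an oppositely oriented cryptic
heptamer inside a chosen V, and append a near-identical copy of a V
block at a stated identity, recorded as a segmental duplication (equal
length, position-wise mapping). Reading frames default to phase 0 and
all segments to functional; both are per-segment annotations.

## Recombination operations

Every operation returns derivative contigs as *piece lists* over the
parent chromosomes plus a truth record with normalized junctions, so
sequence conservation (Σ products = Σ parents − deleted + inserted) is
checkable exactly.

- **Deletion** cuts at the heptamer/coding boundaries of two facing
  RSSs, removes the intervening DNA (both RSSs included), trims the
  coding ends and inserts an N-region. The excised circle (optional,
  off by default since only chromosomal products are sequenced) carries
  the precise signal joint.
- **Inversion** reverse-complements the segment between two
  same-orientation RSSs in place: one coding joint (trims + N) and one
  precise RSS-RSS signal joint are both retained on the chromosome.
- **V replacement** joins the invading V's intact RSS (a signal end) to
  a CAC-rooted cryptic heptamer inside another V, deleting the
  interstitial DNA; a short stub of the removed coding segment may be
  retained next to the N-region. Category V-V, hybrid joint.
- **Two-step V(D)J assembly** composes a D-J deletion and the
  subsequent V-to-DJ join, leaving two coding joints with a short
  retained D between them.
- **Translocation** builds der(A) = A-left + N₁ + B-right and
  der(B) = B-left + N₂ + A-right; unequal breakpoints on a chromosome
  leave an interval present on neither derivative (the per-derivative
  loss the ledger reports).

N-region lengths follow the observed support `{2,3,4,5,8,11,23}`
(uniform over that set, hence short 2–5 nt additions outweigh longer
ones); signal joints never receive N unless explicitly forced.
P-nucleotides are not modeled.

## Bait design and capture model

One 200 nt window per RSS, anchored at the coding edge and extending
across the whole RSS into non-coding sequence; overlapping windows are
merged and tiled with 120-mers at 5× fold (spacing `round(120/5)`,
final bait flush with the window end; sub-bait windows get one centred
bait). Signal-side windows reproduce the assay's enrichment bias toward
inversional events, which retain their RSSs; `symmetric=True` centres
windows on the RSS instead and is used in the soundness panels so
coding joints are as well covered as signal joints. Plain-FASTA input
without annotation falls back to motif scanning with symmetric windows.

Capture sequencing draws fragments uniformly along all contigs
(derivatives plus germline), log-normal insert length (median 254 nt,
σ_log = 0.10, consistent with a 500 nt-median sonication library after
capture size selection), 100 nt read pairs, uniform substitution errors
at 0.1% (no indels, no duplicates, no adapter artifacts). A fragment
overlapping a (coordinate-lifted) bait is retained with probability
0.95; the off-target retention probability is calibrated analytically
so the realized on-target fraction approximates the 50% (38–54%)
operating point. Fragment count is set so retained on-target pairs give
the requested fold coverage over bait-covered bases. Everything is
driven by one seeded generator; identical configuration gives
byte-identical FASTQ.

## Detection

The built-in aligner (21-mer seeding over a full-genome index, banded
edit-distance verification with edlib, all placements within 3 edits of
the best reported, best > 5 edits = unaligned) is intended for
desk-scale synthetic references; pre-aligned SAM from any production
aligner can be ingested instead. Footprints are fixed to the query
length (substitution-dominated libraries), which keeps placements
SAM-round-trippable.

Insert statistics come from concordant unique pairs (median and
1.4826·MAD). A pair is discordant when its mates map to different
chromosomes, in unexpected relative orientation (same-strand ⇒
inversion-like), or with implied insert beyond median + 3·dispersion
(deletion-like). Discordant pairs are clustered by single-linkage
*requiring both footprints* within one window (median + 3·dispersion);
linking on one footprint alone lets unrelated insert-length outliers
bridge into genuine clusters and drag the candidate intervals off the
breakpoint. Candidate intervals are constructed to contain the true
breakpoint given the mate geometry.

Split-read refinement decomposes each candidate spanning read
(unaligned or poorly aligned, mate anchored in either candidate locus)
into a maximal exact prefix match in the oriented side-A flank and
suffix match in the side-B flank, each ≥ 20 nt. The gap is the
untemplated insert; an overlap is microhomology; the per-read junction
is normalized to the canonical leftmost frame and tallied. Three
guards shape the vote table:

- same-chromosome seams spanning < 40 nt are ignored (that is what an
  ordinary read with a sequencing error decomposes to, and the
  absorb/normalize step collapses two-error reads to such trivia);
- an insert containing a ≥ 14 nt run templated from the intervening
  reference is split into its two constituent junctions before voting,
  so a V-D-J product with a short retained D contributes support to
  both seams rather than one compound call;
- keys are accepted top-down: the majority key always, others at
  ≥ max(2, top/4) votes; near-duplicate minority keys (within 5 nt)
  set a conflict flag on the winner instead of becoming calls.

Clusters that never acquire a split read stay at interval resolution
and must clear a stricter pair threshold (4), suppressing chance
clusters of insert-length outliers. Consensus junction sequences are
per-column majority votes over seam-anchored spanning reads, ties
toward the lexicographically first base. Output is sorted and invariant
to input read order.

## Ambiguity in segmental duplications

A call whose flank lies inside an annotated duplication is rescored:
the called junction sequence (150 nt flanks + insert) is compared, per
supporting split read, against the homologous junction obtained by
mapping the flank through the duplication. The call is *resolved* when
the called placement beats every alternative by ≥ 2 edits for ≥ 2
reads — i.e. when the reads cover enough copy-distinguishing
(diagnostic) bases — and *unresolved* otherwise (reported, never
dropped). Copy-identical flanks are information-theoretically
unresolvable and always flag unresolved.

## Annotation

Each side of a base-pair-resolved junction is classified from the
retained flank direction: signal end if the flank keeps at least half
of an annotated RSS, coding end if it overlaps a coding interval
(both with 10 nt slack, since the leftmost shift can slide a seam a few
bases across an annotated edge), otherwise non-RSS; sides with no
explaining RSS are searched for a CAC-rooted cryptic heptamer (≤ 1
mismatch outside CAC, ± 50 nt). Joint type: signal/signal ⇒ signal,
coding/coding ⇒ coding, mixed ⇒ hybrid, any non-RSS ⇒ translocation
junction. For coding sides the mediating RSS is the segment RSS at the
junction-facing end (excised with the intervening DNA but still the
recombinase's substrate), so 12/23 is checkable for coding joints too:
compliant iff the two spacer classes (nearest of 12/23 within ± 1 nt)
are {12, 23}; a cryptic heptamer has no nonamer, hence not-applicable.

Frame: the codon phase after the retained left coding sequence,
advanced through the N insert, must equal the annotated phase at the
first retained base of the right segment. In-frame joints are
productive only if both segments are functional and neither is retained
below half its length (`min_coding_fraction = 0.5`, configurable; a
joint keeping 35 of 175 coding bases is thus unproductive by
truncation). Event category follows the partner segment types; a V-D
junction is promoted to V-D-J when the same D's other flank carries a
D-J junction. Lineage flags compare the locus (IG* = B, TR* = T, by
nomenclature prefix) with the sample lineage. A V-J event in a
D-bearing locus whose J RSS is observed retained in a signal or hybrid
joint is flagged order-violating: the retained RSS proves no D-J join
preceded V incorporation.

The reciprocal ledger takes two translocation junctions, checks they
retain complementary sides of each parent chromosome, and reports per
chromosome the interval on neither derivative (lost), shared
double-retained bases if any, total inserted N, and the conservation
identity Σ derivatives = Σ parents − lost + shared + inserted.

## Problem sizes and what the tests show

Test and acceptance panels use per-event loci of 5–10 kb, 50× coverage
over bait-covered bases (a few hundred to a few thousand read pairs per
scenario), and the read geometry above; the soundness panel aggregates
102 events (17 batches × 6 categories). At these depths every planted
junction has well over 10 spanning reads, so the suites measure
detector correctness, not sensitivity at marginal depth. Passing them
shows the machinery is exact on data matching the generator's
assumptions — uniform base composition, substitution-only errors, clean
diploid-like mixtures of one rearranged haplotype plus germline. Real
capture data adds PCR duplicates, indel errors, coverage waves, allelic
mixtures and polyclonality, none of which are modeled; interval-level
candidate quality and the ambiguity policy in particular should be
expected to degrade more gracefully than breakpoint exactness.

## Known limitations

- No P-nucleotide model; junction inserts are pure N-region.
- The internal aligner is not a production aligner; real genomes should
  be aligned externally and ingested as SAM.
- Hybrid capture is reduced to a two-level retention probability; no
  GC bias, no bait-affinity variation.
- Segmental duplications are modeled as equal-length, colinear copies.
- Productivity uses annotated frames and functionality only; no ORF
  translation or splice modeling.
- The detector calls junctions, not copy number, small indels or SNVs.
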