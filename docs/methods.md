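# Methods

`cccrna` detects covalently closed circular RNA (cccRNA) replicons —
viroids, viroid-like agents, and Obelisks — in de-novo assemblies of
double-stranded-RNA sequencing (dsRNA-seq / FLDS) libraries, without using
sequence similarity to any known element, and then characterizes the
candidates (structure statistics, circular ORFs, motif scans, clustering
and nomenclature, spacer-match post-processing). This note records the
models, the parameter choices, and the numerical decisions behind each
stage.

## Detection model

A cccRNA replicated by a rolling-circle-like mechanism leaves three
signatures in a dsRNA-seq assembly, and the cascade tests all three:

1. **Terminal redundancy.** An assembler walking around a circular
   template overshoots its origin, so the contig carries a copy of its 5'
   sequence at its 3' end. Detection anchors a seed of `min_seed = 30` nt
   at each offset within the first `terminal_window = 130` nt, searches
   for its recurrence downstream, and requires the alignment to extend
   through the final base with at most `max_mismatch = 0` mismatches.
   Exact matching is the conservative reading of seed-and-extend
   circularity detection; the cap is configurable. When several downstream
   matches qualify, the one giving the shortest monomer wins, so full
   multimers collapse to one copy. A contig shorter than `2 * min_seed`
   is reported "not evaluable", distinct from "not circular". The monomer
   period is additionally required to be at least `min_seed`, which keeps
   low-complexity tandem repeats (period < 30 nt) from masquerading as
   tiny circles.

2. **Rod-like secondary structure.** Viroid-like replicons fold into a
   long unbranched rod in which most bases pair. Candidates must show a
   paired-base fraction strictly above 0.60 at 37 °C under circular
   minimum-free-energy folding.

3. **Even read mapping.** Reads from a genuine replicative intermediate
   start everywhere on the circle; chimeras and expression artifacts pile
   up. Two bounded metrics formalize this (below); candidates need
   normalized CV < 0.6 and normalized start entropy > 0.7, strict
   inequalities.

The full stage order is: circularize → deduplicate → known-sequence
exclusion (optional, tabular homology hits at E ≤ 1e−5) → length ≥ 200 nt
→ mean depth ≥ 10 → paired fraction > 0.60 → evenness. Deduplication is
placed immediately after circularization because rotations and strand
flips of one circle must count once everywhere downstream. The coverage
threshold is interpreted as *mean* per-nucleotide depth ≥ 10 (the natural
reading when depth varies along the circle). Every report embeds the full
configuration and a hash of it, so funnels from different runs are
comparable.

Known-sequence exclusion consumes a precomputed tabular hit list
(query id + E-value) rather than running a search engine: the threshold
logic is part of the cascade, the database search is not, and database
content is inherently unreproducible.

Multi-mapped reads: each primary alignment counts toward coverage and
starts; secondary alignments are ignored, supplementary alignments count
for depth but not starts (start entropy measures fragment origins, not
split mappings).

## Evenness metrics

With per-position depth d_i on a circle of length L and mean depth μ:

* normalized CV = (sd(d)/μ) / √(L−1), clamped to [0, 1]. √(L−1) is the
  population CV of all coverage mass concentrated at a single position —
  the unique depth shape maximizing CV at fixed total mass — so the
  metric is 0 for uniform depth and 1 for a one-position spike, and is
  comparable across lengths and depths. The population (not sample)
  standard deviation is used; the two differ by √(L/(L−1)), immaterial at
  the lengths involved, and the population form makes the spike case
  exactly 1.
* normalized start entropy = H/ln L where H = −Σ p_k ln p_k over the
  empirical distribution p_k of read start positions. Natural logarithms;
  the base cancels in the ratio. 0 when every read starts at one
  position, 1 when starts are spread one per position.

Minus-strand reads contribute the leftmost reference coordinate of their
alignment as the "start"; origin diversity is strand-agnostic. Both
metrics are undefined (and fail the stage, with the reason recorded) when
there is no coverage or no mapped read.

A caveat that matters when interpreting the entropy threshold: the
plug-in entropy of n uniform draws is ≈ ln n when n ≪ L, so a sparsely
covered contig can fail the > 0.7 criterion even if its true start
distribution is uniform. At the mean-depth ≥ 10 floor this requires
n ≳ L^0.7 reads, which short-read data satisfy comfortably.

## Secondary structure

Folding is delegated to a backend behind one interface
(sequence, temperature, circular flag) → (dot-bracket, MFE):

* `vienna` — ViennaRNA's MFE fold with true circular folding
  (the circular flag of the model details) and temperature support; the
  backend of record, used for both sense and antisense strands.
* `maxpair` — a built-in base-pair-maximization dynamic program
  (Watson–Crick + GU wobble, minimum hairpin loop of 3, N never pairs) on
  the sequence linearized at a configurable cut (default: the canonical
  origin). It reports no free energy and does not fold circularly; it
  exists so that every downstream statistic is unit-testable without the
  thermodynamic engine, and it is verified against exhaustive pair-set
  enumeration for short sequences.

Both structure statistics count nucleotides, not pairs:
paired fraction = 2·|pairs|/L, and ORF self-complementarity = among
paired bases belonging to pairs with at least one end inside the ORF, the
fraction whose own base and partner both lie inside. Both depend only on
the pair list and are rotation invariant when coordinates and ORF are
rotated together.

## Circular ORF calling

ORFs are start (ATG by default; configurable, since very short replicons
may use alternative starts) to stop, in all 6 frames, on a circle. When L
is not a multiple of 3 a single reading path cycles through all three
frames and returns to its origin after 3L nt, so scanning proceeds on a
tripled copy of the monomer and aborts after three wrappings when no stop
is met; such ORFs are flagged truncated and can reach a coverage
(ORF length / monomer length) of 3.0. Every start codon in [0, L) is
walked to its first in-frame stop and only the longest ORF per stop-codon
instance is kept — this definition is independent of where the circle was
linearized, which plain left-to-right state-machine scanning is not. For
input flagged non-circular the procedure reduces exactly to a 6-frame
linear scan. Minus-strand ORFs are reported as their forward-strand
footprint interval; wrapped ORFs export to GFF3 as multi-part features
sharing one ID. Working thresholds: 60 aa for the main-protein search,
40 aa for the remaining proteins.

## Leucine-zipper scan

Coiled-coil regions (externally predicted, supplied as intervals; the
whole protein when none are given) of ≥ 21 aa are scanned in all 7 heptad
registers. A zipper is called for a run of ≥ 3 consecutive heptads with
(i) Leu at the "a" position in ≥ 50% of the run's heptads AND (ii)
Leu/Ile at the "d" position in ≥ 50% AND (iii) at least 3 matches at "a"
or "d" combined. The 50% clause is genuinely ambiguous (one joint
fraction vs. two independent ones); the two-independent-fractions AND
reading is implemented as the closest literal one, with the fractions and
floors exposed as parameters. Maximal qualifying runs are reported per
register.

## Ribozyme position

A ribozyme hit (externally predicted, supplied as an interval) is nested
when its footprint is a subset of the ORF footprint modulo L,
non-overlapping when disjoint, overlapping otherwise; sense/antisense is
relative to the ORF strand. The reported distance is the minimal circular
distance from either hit boundary to the ORF start codon, so "ends 51 nt
upstream of the start codon" reads out as 51. Whether the original
measurements were taken on the circle or a linearization is not
determinable; the circular minimum is the coordinate-free choice.

## Profile comparison, dendrogram, grafting

Profile–profile scores convert to distances by
d_AB = −ln(S_AB / min(S_AA, S_BB)), clamped at 0 when the cross-score
exceeds the smaller self-score. Pairs with no detected relationship are
filled with an artificial low score, default (minimum observed
off-diagonal score)/10 — far enough to land beyond the merge radius,
finite so the dendrogram stays well-formed. UPGMA is implemented directly
(average linkage, merge height = pair distance / 2, ties broken on the
lexicographically smallest member id so output is input-order invariant)
and is cross-checked in the tests against SciPy's average-linkage
cophenetic distances. Cluster-merge candidates join when distance ≤ 2.2
or alignment coverage ≥ 0.66 (both boundaries inclusive). Alignment
columns with a gap fraction strictly above the threshold (0.67 within
clusters, 0.90 before tree building) are removed with an index map back
to the original columns. Midpoint rooting places the root halfway along
the longest leaf-to-leaf path; grafting replaces a named leaf by a
subtree, preserving the leaf's stem length.

## Rotation-invariant identity and nomenclature

Identity between circular sequences aligns each sequence against the
doubled other (edit-distance alignment), over both strands, and scores
matches / min(len a, len b) — the shorter-sequence denominator is robust
to terminal gaps on the doubled target; the maximum over both orderings
makes it symmetric. Clustering is greedy, length-descending,
centroid-based: at 80% identity for the family level (X), then within
each family at 95% for the species level (Y), with strains numbered (Z);
labels are `Obelisk_X_Y_Z`, 1-based, zero-padded to six digits, and
deterministic (clusters ordered by descending size then centroid id).

## CRISPR spacer post-processing

Matches of spacers against doubled (sense + antisense) circle sequences
arrive as BLAST outfmt-6 / MMseqs m8 tables. The `local` preset keeps
matches covering ≥ 90% of the spacer with ≥ 16 identical nucleotides; the
`hq` preset keeps full-coverage matches at ≥ 80% identity. Coordinates
are reduced modulo the monomer length; the duplicate hit one period away
on the doubled target is removed; loci whose non-overlapping portions
total ≤ 10 nt are combined, keeping all contributing spacer ids. The
summary reports per-circle locus counts and the fraction of kept matches
with ≤ 1 mismatch (a proxy for recent acquisition).

## Synthetic data

The generator produces, from one integer seed:

* **Rod replicons**: monomer = arm1 | loop1 | revcomp(mutated arm1) |
  loop2, with the two arms covering `stem_fraction` (default 0.8, the
  rod-like regime) of the circle and the designed pair list recorded as
  ground truth. Loops are drawn from an A/C alphabet, which cannot pair
  with itself, so the designed stem is the dominant pairing and
  `stem_fraction = 0` yields an unstructured control that cannot pass the
  60% filter. Default length 900 nt (the ~0.9–1.1 kb range typical of
  these elements), arm mutation rate 0.02.
* **ORFs**: an ATG + stop-free codons + stop gene written into the 5'
  arm (it may extend into the adjacent loop but not into the
  complementary arm, so the pairing truth is preserved), then rotated to
  span the origin by 30 nt. Consequently the synthetic ORF pairs with
  the *opposite* arm and its designed self-complementarity is low —
  unlike real Obelisks, whose single large ORF covers both arms of the
  rod and is therefore largely self-paired. Tests of the
  self-complementarity statistic use constructed pair lists, not the
  generator.
* **Concatemer contigs**: a rotation of the monomer repeated to a
  fractional copy number (default 1.3), i.e. assembler overshoot.
* **Reads**: fixed-length read starts drawn uniformly or from a wrapped
  von Mises peak (κ = ∞ collapses to a single origin); wrap-around reads
  split into primary + supplementary SAM records, and the same profile is
  emitted as the `pos depth starts` TSV dialect.

The labelled fixture suite pairs rod positives (uniform coverage, mean
depth ≈ 20, lengths 300–1500 nt) with negatives violating exactly one
criterion each (linear, short, low-depth, unstructured, single-peak
coverage). What passing recovery tests show is that the cascade's
thresholds separate these engineered classes perfectly; they do not show
robustness to real-data phenomena the generator omits — sequencing
error, coverage GC bias, partial-degradate contigs, chimeric assemblies,
or structured-but-linear RNAs with accidental terminal repeats.

## Problem sizes and numerics

The shipped tests and the acceptance script use 20 positive + 20 negative
fixtures (lengths 300–1500 nt), a 900-nt reference rod, and 2000
simulated reads of 100 nt — sizes at which the thermodynamic folds and
alignments complete in seconds while every filter operates well away from
its numerical noise floor. Entropy and CV computations are plain float64;
the only clamps are the documented [0, 1] bounds and the distance clamp
at 0. The pair-maximization fallback is O(L³) and intended for L up to a
few hundred; thermodynamic folding handles full-length candidates.

## Known limitations

* Terminal-redundancy detection is exact-match by default; highly
  divergent concatemer copies (mutation between wraps) need the mismatch
  cap raised.
* The fallback folder ignores thermodynamics; its paired fractions upper-
  bound plausible pairing and it reports no MFE.
* Circular identity derives matches from edit distance (matches ≥
  min_len − edits), a lower bound that is tight for the
  substitution-dominated divergence it is used on.
* Greedy centroid clustering is order-deterministic but, like all greedy
  ANI clustering, not globally optimal near thresholds.
* The evenness criteria assume short reads at depth ≥ 10; very sparse
  libraries fail the entropy criterion for sampling reasons (see above).
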