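# Methods

## The mappability model

`temap` scores the mappability of a base position as the inverse of the
number of placements at which the read (single-end) or read pair
(paired-end) originating at that position aligns, allowing up to `m`
mismatches per read. Scores attach to the forward-strand start coordinate
of the read or fragment; reverse-strand origins are redundant by symmetry
and are not scored separately.

Alignment semantics, fixed throughout:

* **Gapless.** Placements are Hamming-distance matches; there is no indel
  model. This mirrors `-v`-style short-read alignment and is the reason the
  simulator mutates copies with substitutions only.
* **Both strands.** A placement is a (position, strand) pair. Palindromic
  reads that match a window on both strands yield two placements, exactly
  as an aligner reporting (position, strand) records would.
* **Per-read mismatch budget.** For pairs, `m` applies to each mate
  independently, not jointly.
* **N handling.** A focal window containing N is UNDEFINED (NaN in the
  track): that read never existed in a k-mer library built from the
  genome. Target windows containing N never match anything.
* **Insert-size range.** A paired placement requires forward–reverse
  orientation, leftmost-read start ≤ mate start, and fragment length
  (rightmost end − leftmost start) within `[insert_min, insert_max]`. The
  default range is `[max(2r, L−50), L+50]`: symmetric 50 bp slack around
  the library fragment length. The slack is configurable because no single
  published default covers all fragment sizes used here; with slack zero
  (`[L, L]`) paired-end scores are provably never below single-end scores.
  Placements sharing a start but differing in fragment length are distinct
  placements — the conservative choice, and the mechanism by which
  paired-end mappability can drop *below* single-end mappability inside
  tandem repeats.

### Two routes to the same number

* **Method 1 (count-summing).** Build the exact k-mer occurrence table
  (k = r single-end, k = L paired-end; counts are stranded placement
  counts, so a palindromic k-mer present n times counts 2n). The score at
  p is the inverse of the summed counts of every distinct library k-mer
  with an alignment at p, in either orientation.
* **Method 2 (placement-counting).** The score at p is the inverse of the
  number of placements of the focal read/pair itself, found by exhaustive
  search.

For single-end reads the two are mathematically identical — each genome
occurrence contributes once per matching orientation on both routes — and
the test suite asserts bit-identical tracks on random and adversarial
genomes. For paired-end reads they genuinely differ: method 1 asks "which
library fragments produce pairs aligning here", method 2 asks "where does
*this* pair align", and near chromosome ends or with asymmetric insert
windows those sets decouple. The package reports their agreement rate on
fixtures rather than asserting equality.

### Exhaustiveness and the oracle

The production scorer uses a pigeonhole seed index: the read is tiled with
`m+1` disjoint seeds of length `⌊r/(m+1)⌋` (capped at 31 so a seed packs
into a 2-bit int64 code), any alignment with ≤ m mismatches must match one
seed exactly, and exact seed hits are verified by full Hamming comparison.
This is contractually exhaustive — no heuristics, no score threshold.
`oracle_score` recomputes any position by a naive full scan over every
(position, strand) window with no index at all; the test suite compares
the two at *every* position of multi-kilobase fixtures, single- and
paired-end, both methods. The oracle is the arbiter; the index is only an
accelerator.

## Locus aggregation

A locus is scored over read/fragment *start* positions inside its
interval `[start, end)`; reads may extend past the 3' boundary (the
convention that matches start-position score attribution). UNDEFINED
positions are excluded from numerator and denominator. A locus is uniquely
mappable only if every defined position scores 1 — conservative by design,
and immune to inflation from unique flanks because one multi-mapping
position anywhere in the interval vetoes the call. Loci with no defined
positions report missing percentages and are never called unique.

Rollups to subfamily/family/class report copy number, the percent of loci
uniquely mappable, and the mean per-locus percent-unique; tables sort by
(class, family, subfamily, chrom, start) so outputs are reproducible. The
comparison filter for paired-vs-single analyses drops loci shorter than
300 bp (configurable) and loci already at 100% unique in every paired-end
library, both uninformative for geometry effects.

## The simulator

`synthgenome` emulates the features of real TE annotations that drive
mappability, without claiming to be a genome model:

* i.i.d. background at a configurable GC content (default 0.41, the
  human-like value);
* subfamilies planted as copies of a consensus, each copy independently
  5'-truncated (retained 3' fraction drawn per copy — the shape produced
  by 3'-initiated target-primed reverse transcription) and then mutated by
  i.i.d. substitutions at `sub_rate` (an age proxy; no indels, matching
  the Hamming alignment model);
* uniform non-overlapping placement on either strand;
* segmental duplications applied verbatim *after* planting, so duplicated
  loci reappear under distinct locus ids — the mechanism that leaves even
  anciently diverged copies non-unique.

Each planted locus carries a truth map from element-oriented position to
consensus coordinate, strictly increasing because there are no indels.

What the simulator does **not** model: insertion-site preference, target
site duplications, 3' transduction, nested/fragmented elements, and
polymorphic insertions. Tests passing on simulated genomes therefore
validate the *scoring machinery* (definitions, exhaustiveness,
aggregation, statistics), not any claim about a particular real genome.

Demo defaults (40 kb genome; scaled-down counts at smaller lengths): a
young L1-like subfamily at `sub_rate` 0.002 — recently active subfamilies
carry copies nearly identical to their consensus, far inside the mismatch
allowance, which is precisely why they cross-map — an old L1-like
subfamily at 0.12, a short high-copy SINE-like subfamily at 0.08, and one
segmental duplication. The six demo libraries are single-end 50/76/100 bp
and paired-end fragments 200/242/300 bp (same read lengths; the 90 bp gap
of the 242 bp library reflects a realistic RNA-seq median insert).

## Statistics and consensus analyses

* **Permutation test.** Two-sided test of the difference in group means
  under label permutation. When the number of label splits `C(n, n_a)` is
  ≤ 20 000 the test enumerates all splits and p is exact (the observed
  split counts itself, so p > 0). Otherwise it samples `n_perm` shuffles
  with the add-one rule `p = (1 + hits)/(n_perm + 1)`, floored at
  `1/(n_perm+1)` — a reported p of 0, or any p below the floor, is
  unattainable by construction. Tie comparisons use a relative 1e-9
  tolerance so floating-point noise cannot drop a tied permutation.
* **Consensus alignment.** Loci are mapped onto their subfamily consensus
  by a deterministic semi-global alignment (free end gaps on the consensus
  only; match +1, mismatch −1, gap open −5 on the first gapped base, −1
  per extension, first-optimal tie-break), via Biopython's
  `PairwiseAligner`. On the simulator's indel-free copies this provably
  recovers the truth map, and the tests assert exact recovery up to 10%
  divergence; on real, indel-containing loci it is an approximation and an
  optional score floor flags unalignable sequences.
* **Consensus profile.** Per consensus position: median and quartiles
  (linear interpolation) of the pooled locus scores mapped there, plus the
  number of covering loci. With 5'-only truncation the depth is
  non-decreasing toward the 3' end, a property the tests check.
* **Sub-clade classification.** Reads the locus bases mapped to diagnostic
  consensus positions (e.g. a 3' UTR trinucleotide, ACA vs ACG for the
  L1HS Ta/preTa split) and returns the matching label, or "unclassified"
  when the site is truncated away, gapped, or unknown. The diagnostic
  coordinates are user input: they belong to the consensus used, not to
  the package.

## Numerical and design choices

* Internal coordinates are 0-based half-open everywhere; 1-based
  conventions exist only at parse/serialize boundaries (RepeatMasker
  `.out` begin/end, wiggle fixedStep).
* Track serialization prints scores with full `repr` precision, so a
  write/read round trip is bit-exact; all defined scores are reciprocals
  of positive integers by construction.
* RepeatMasker rows flagged `*` (overlapped by a higher-scoring match) are
  kept by default with a switch to drop them; rows are scored
  independently, with no merging of fragmented elements.
* One global seed drives every stochastic component; pipeline stages
  derive sub-seeds by fixed offsets so stages are decoupled but the whole
  run is reproducible byte for byte.
* Problem sizes in the tests and the acceptance script (2–16 kb genomes,
  reads 12–100 bp) were chosen so every property that is scale-free —
  exactness of the two methods, oracle agreement, 1/n recovery,
  monotonicity in read length — is checked at full positional coverage in
  seconds. Genome-scale runs change constants, not these properties.

## Known limitations

* No indel or base-quality model; scores describe `-v`-style gapless
  alignment, not quality-aware mapping.
* Paired-end method 1 is quadratic-ish in local repeat density; the
  implementation is written for annotation-scale validation, not for
  whole-genome production runs.
* The consensus aligner's guarantees hold only for substitution-only
  divergence; heavily rearranged loci should be filtered with the score
  floor.
* Splicing-aware mappability (reads spanning junctions) is out of scope.
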