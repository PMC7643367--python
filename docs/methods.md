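# Methods

## The problem

Two adjacent windows on the pig X chromosome carry structural variants (SVs)
that segregate cleanly between population groups: one window separates
European from Asian pigs (pattern A), the neighbouring one separates
South-Asian pigs from everything else (pattern SA). Both windows sit in a
low-recombination region around the centromere, so each behaves as a single
haplotype block. Most of the pattern SVs are recent SINE/LINE insertions, so
the questions the package answers are: which SVs show a pattern, do short
reads confirm the pattern in independent individuals, which TE subfamilies
produced the insertions and when were they active, and on which branch of the
dated species tree must each pattern have arisen.

## Synthetic data model (`synth`)

The generator emulates the study design rather than pig genomes per se:

* Reference: i.i.d. bases at a configurable GC fraction (default 0.42,
  typical mammalian). Real genomes have repeats and compositional structure;
  an i.i.d. reference makes every 200-bp flank unique, which is exactly the
  "unique flanks" regime the SV-recovery guarantees are stated for.
* Panel: SVs are laid out on fixed slots inside the two windows so deletions
  can never overlap; lengths are log-uniform (most SVs short, a tail up to
  the cap), matching the strongly right-skewed empirical SV size spectrum.
  Presence-type patterns are planted as insertions in the named group,
  absence-type patterns as deletions (the reference plays the European-like
  assembly, which carries the sequence).
* TE insertions draw a prefix of a library consensus, evolve it with the
  substitution model below, and append a 3′ poly-A tail (default 12 bp) so
  the poly-A detector and the coverage-masking logic are exercised. The
  packaged library consensi are synthetic stand-ins (deterministic random
  sequences regenerated from fixed seeds) with SINE-like (231/246 bp) and
  LINE-like (2 kb) lengths; they model the *geometry* of family attribution,
  not real repeat sequence.
* Substitution model: each site substitutes independently with probability
  equal to the target divergence; transitions:transversions 2:1; sites inside
  a consensus CpG dinucleotide substitute at `cpg_multiplier` × the base rate
  (default 10 — large enough for the CpG correction to be visibly exercised;
  the real CpG acceleration in mammals is of that order). Realized per-copy
  divergence is recorded as truth.
* Reads: uniformly placed single-end reads, count = round(depth·L/read_len),
  i.i.d. substitution errors, flat Phred qualities encoding the error rate.
  Paired ends, indel errors and diploidy are deliberately absent: the
  genotyping rule consumes only per-base coverage on a haploid (X-linked)
  region, so none of them changes the decision logic. Consequently, passing
  tests demonstrate the correctness of the decision rules, not robustness to
  real-library artefacts (chimeras, duplicates, indel errors, mapping bias).

Everything is driven by `numpy.random.default_rng` with explicit seeds and is
bit-reproducible.

## Assembly comparison (`asmdiff`)

Anchors are maximal exact matches of ≥100 bp seeded at 21-mers that occur
exactly once in both sequences — a deterministic, desk-scale analogue of
maximal unique matches. Chains maximize total anchor length subject to
collinearity (strictly increasing in both coordinates); anchors may overlap
by up to 50 bp inside a chain because breakpoint micro-homology (e.g. an
insertion's poly-A tail continuing into reference A's) lets both flanking
anchors extend past the true breakpoint. Overlaps are trimmed off the
downstream anchor symmetrically — on both coordinates at once — which
preserves the reference-gap/query-gap *difference* and therefore the SV type
and length; only the reported breakpoint can shift by a few bases. A
containment overlap (the downstream anchor disappearing entirely) rejects
the chain. Chains lighter than 500 bp total anchor length are discarded.

Gap arithmetic between consecutive anchors: reference gap only → deletion;
query gap only → insertion (alt sequence recorded); both gaps → indel of the
net difference. Records outside 1 bp–10 kb are dropped. Indel records are
kept in the catalog but excluded from pattern classification by default,
since their call does not state cleanly which sequence is present where.

The merge collapses same-type records by single-linkage under a
reciprocal-overlap ≥0.5 rule (insertions: breakpoints within 10 bp and
lengths within 20 %), representative = longest, then leftmost. These
tolerances are declared conventions of this package, exposed as arguments;
the result is invariant to genome input order and idempotent, which the
tests check directly. Coordinates are 0-based half-open throughout.

## Pattern classification (`patterns`)

Classification operates on *sequence* presence: insertion catalog columns
pass through, deletion columns are inverted (a deletion call means the
sequence is absent). Calls are strict all-or-none — present in every genome
of one group and absent from every genome of the complement — because the
assembly panel is small and high-confidence; quantifying deviation is the
genotyper's job. When a profile satisfies both an SA and an A definition
(possible only in degenerate cohorts with no North-Asian genomes), SA wins
by default. The crossbreed group sides with South Asia (configurable), and
for A-type calls it counts as Asian (flag-controlled).

Both window parameterizations found in the study region ship as presets
("methods": 44–58 / 58–92 Mb; "results": 45–57 / 57–87 Mb); the wider pair
is the default. Enrichment is a 1-df goodness-of-fit χ² whose null
expectation is proportional to the chromosome's share of catalog *SV count*,
not of genome length — the choice is recorded in the result object, and the
per-count null is the conservative one when SV discovery itself is uneven
across chromosomes. Panel selection is strictly >100 bp.

## Read-backed genotyping (`genotyper`)

QC order: adapter-containing reads dropped (exact substring), then the
longest all-low-quality 3′ suffix (Q < 20) trimmed, then reads with >30 %
low-quality-or-N bases (Q ≤ 20) dropped. The local reference is 200 bp flank
+ SV + 200 bp flank cut from a genome that *carries* the sequence; R1–R5 are
laid out 195/5/SV/5/195 so R2/R4 straddle the two breakpoints. The mapper is
exact: every end-to-end ungapped placement with ≤2 mismatches (pigeonhole
seeding + full verification, equal to a brute-force scan, which a test
asserts). Present requires cov(R3) ≥ 0.60, cov(R2) = cov(R4) = 1.0,
cov(R1) ≥ 0.5, cov(R5) ≥ 0.5, all inclusive; everything else is absent —
binary, with a low-coverage warning flag (<5 placements) that never enters
the decision. Each SV is judged only on its own local reference;
multi-mapping across SV loci is accepted. Concordance compares calls with
the expectation the pattern definition implies for the individual's group
(e.g. A-p ⇒ present in Asians), overall, per pattern and per group.

## TE attribution and subfamilies (`teclass`)

Alignment is optimal pairwise local alignment under match +1 / mismatch −1 /
gap −2 (Biopython's `PairwiseAligner` is the engine; an independent tiny
Smith–Waterman verifies scores in the tests). Identity counts matches over
aligned columns including gap columns; coverage is aligned query bases over
query length. Poly-A tails are masked before family search (flag-controlled)
because tail-length variation otherwise depresses coverage. Complete TE:
identity > 0.90 and coverage > 0.80; partial: identity > 0.80; otherwise
unassigned. Greedy clustering processes consensi longest-first and joins a
sequence to the first representative at ≥95 % global identity.

Subfamily splitting considers all pairs of (consensus position,
non-consensus state) where each single state has at least
`min_subfamily_size` (default 30) carriers; the pair statistic is the upper
binomial tail of the co-carrier count under independence of the two
single-site frequencies. The most significant pair splits the family if
p < 1e−4 and both halves keep ≥30 copies; consensi are recomputed and the
recursion continues (depth-capped). This two-site co-occurrence test is this
package's formulation of the cosegregation idea; three-site interactions are
out of scope.

## Dating (`chronology`)

K2P distance over ungapped, unambiguous columns, with an explicit
`SaturationError` when `1−2P−Q ≤ 0` or `1−2Q ≤ 0`. F_CpG is computed on the
consensus (2 × CG dinucleotide count / length — CG occurrences cannot
overlap, so no double counting), and ages are point estimates
`(D_CpG/r)·g` with defaults r = 2.5·10⁻⁸ subs/site/generation and
g = 5 years/generation. Landscapes are half-open fixed-width bins (default
0.01 substitutions/site). Note the clock is linear: 0.004 subs/site maps to
0.8 Ma and 0.025 to 5.0 Ma under the defaults.

## Origination intervals and scenarios (`timeline`)

Trees are newick with internal-node labels carrying ages in Ma (leaves age
0; ages must strictly decrease rootward→tipward; ultrametricity is not
required). Under single origin with no loss, a marker's origination edge is
exactly the stem of the carrier clade, so the interval is (parent age, crown
age); a single-leaf carrier clade has crown age 0, and unknown leaves are
ignored for monophyly. Non-monophyletic carriers raise an explicit error
directing to `min_origins`, the gains-only parsimony: with losses forbidden
the optimum is one gain per maximal carrier-only subtree, and >1 gain flags
introgression or homoplasy. A loss-allowing (Dollo) mode is intentionally
absent: the identity-by-descent argument these intervals rest on assumes
presence is not re-lost. For pattern SA the caller chooses the subtree
(Europeans also carry the non-South state at the other locus); the packaged
workflow restricts to the Asian subtree.

The packaged tree has 13 tips; the printed calibrations are 11, 3.5, 2, 1,
0.6 and 0.2 Ma. Splits nobody dates (domestic/wild pairs, the internal
structure of the four non-scrofa *Sus* species) carry nominal ages (0.01 Ma;
3.2/2.8/2.2 Ma) chosen once to keep the tree strictly binary with decreasing
ages; no reported quantity depends on them.

Scenario simulation is deterministic set algebra over haplotype sets —
populations are sets, not frequency vectors, because the four-phase argument
is qualitative (which haplotypes *remain*). Split copies, fix replaces,
admix-with-recombination expands the target to the Cartesian product of the
union's alleles, selection filters; a selection event that empties a
population is an error, never silent. Events within a phase apply in order;
events touching disjoint populations commute (tested).

## Problem sizes

The default test and acceptance workloads are sized for a laptop-class
single core: 200-kb chromosomes with 10–11 derived genomes and 60 planted
SVs for assembly round-trips; a 60-kb window, 8 SVs and 11 individuals at
20× for genotyping; 200–500 copies of 300-bp consensi for dating and
subfamily statistics. All complete in well under a minute each; the
algorithms scale linearly in genome length except the O(n²) chain DP over
anchors (n ≈ 2 × SV count here) and the all-pairs cosegregation scan, which
is quadratic in the number of high-frequency variant sites.

## Known limitations

* Forward-strand only by default throughout (generator, anchorer, mapper,
  library search); reverse-complement handling exists behind flags where it
  matters for real data.
* The anchorer needs unique flanks; nested or repeat-flanked SVs at real
  genome scale would require a genuine whole-genome aligner.
* The genotyper has no no-call state and no paired-end rescue.
* Family attribution against the synthetic library says nothing about
  discriminating real, partially homologous repeat families.
* Ages are point estimates; no rate variation, no credible intervals.
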