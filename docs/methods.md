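# Methods

This note documents the models and procedures implemented in refforge,
the parameter choices that matter, and what the synthetic-data tests do
and do not demonstrate.

## Problem setting

A population-specific reference genome is built from a small number of
donors whose genomes are assembled haplotype-resolved, so each donor
contributes two haploid assemblies. Aligning each haploid assembly to a
common backbone yields per-haplotype variant callsets. refforge covers
the stages between those callsets and a finished reference: majority
consensus, marker-based anchoring, unplaced-scaffold cleanup,
meta-assembly planning, and evaluation against a population
allele-frequency panel. It deliberately does **not** perform assembly,
alignment, or variant calling — those enter as files produced by
standard external tools.

## Majority-decision consensus

### Normalization

Variants are reduced to a canonical representation before any voting:
shared trailing bases are trimmed (extending left over the backbone
when trimming would empty an allele), then shared leading bases are
trimmed. This is the standard left-align-and-parsimony algorithm used
by `bcftools norm` and `vt normalize`. The implementation is verified
against an exhaustive oracle that enumerates every equivalent edit of a
small backbone and selects the leftmost parsimonious one; the two agree
on 1,000 random indel representations per run.

### Voting

At each normalized site (chrom, pos, ref), every haplotype contributes
one vote: its alternate allele if it carries a variant there, otherwise
the backbone allele — provided the site lies inside the haplotype's
coverage track. Haplotypes without coverage tracks are assumed to cover
everything; haplotypes not covering a site abstain (so the votes can
sum to less than H).

The decision rule, with H haplotypes:

* a unique allele with count > H/2 wins (H = 6: at least 4 of 6);
* if two or more alleles share the maximum count, the winner is drawn
  uniformly among them — **including the backbone allele when it is
  tied** — using a generator seeded from SHA-256(seed, chrom, pos).
  Keying the generator by site rather than by iteration order makes
  decisions reproducible and independent of callset order or
  parallelization. The inclusive reading (backbone participates in the
  draw) was chosen because a 3–3 site genuinely has two equally
  frequent alleles; excluding the backbone would bias substitution
  upward at exactly the sites where the evidence is weakest;
* otherwise the backbone is retained.

All callsets are treated as one group of size H. Where an upstream
protocol produces callsets in distinct batches (e.g. two
restriction-enzyme-specific scaffold sets), the caller decides which
callsets form the voting group; refforge does not attempt to reconcile
votes across batches because no principled reconciliation rule exists
without additional information.

### Substitution and liftover

Winning variants are applied left to right per chromosome. A winner
whose REF span overlaps an already-applied winner is skipped and
reported — never merged — keeping the operation deterministic and
auditable. The length identity
`len(consensus) − len(backbone) = Σ applied (len(alt) − len(ref))`
holds exactly and is asserted in tests.

The liftover maps backbone to consensus coordinates in aligned blocks.
Within an applied edit, the shared-length prefix of REF and ALT keeps
its coordinates; excess deleted REF bases map to nothing. The chain
output uses the UCSC chain format.

## Electronic PCR

A primer site is any genomic window whose Hamming distance to the
primer (or, on the minus strand, to its reverse complement) is at most
`max_mismatch`, with the 3′-terminal `three_prime_exact` bases matching
exactly — polymerase extension initiates from the 3′ end, so mismatches
there abolish amplification. An N in the genome matches no primer base
and therefore counts as a mismatch. Defaults: `max_mismatch` 1,
`three_prime_exact` 3, product-size margin ±50 bp, and an absolute
100–1000 bp window for markers with unknown product size. These follow
classic electronic-PCR practice; all are overridable because published
marker sets vary in quality.

A hit pairs a forward-primer site with an opposite-strand
reverse-primer site facing it, with the implied product size inside the
marker's window. Scanning is lossless (all candidate pairings are
reported); `dedupe_hits` optionally keeps the best hit per
marker/scaffold by mismatch total, then size error. The scan is
vectorized over numpy sliding windows and is checked against a
quadratic brute-force pairing oracle on 10-kb sequences.

## Map anchoring

Inputs are marker hits plus one or more marker maps (genetic maps in
centimorgans, radiation-hybrid maps in centirays). Because the two
scales are not commensurable, positions are min-max normalized to
[0, 1] per (map, linkage group) before maps are combined; map weights
default to 1.

* **Chromosome assignment**: the linkage group holding the largest
  summed marker weight wins; `conflict` is the weight fraction pointing
  elsewhere; ties or conflict ≥ 0.5 leave the scaffold unplaced.
* **Ordering**: scaffolds sort by the weighted mean of their markers'
  normalized positions (ties broken by name).
* **Orientation**: sign of the weighted Spearman correlation between
  marker coordinates on the scaffold and their map positions; an
  undefined correlation (single marker, zero variance) defaults to +.

This deterministic heuristic replaces the genetic-algorithm
traveling-salesman ordering used by ALLMAPS-class tools. On mutually
consistent maps it provably restores the true order and orientation
(verified by fragmentation/shuffle/flip recovery tests with Kendall
tau = 1); on conflicting real maps a GA can escape local inconsistency
where this heuristic cannot — a known limitation, accepted for
reproducibility and testability.

Pseudomolecules concatenate oriented scaffolds separated by 100 N
(configurable), the conventional inter-scaffold gap. The AGP v2.1
output alternates W and U rows and round-trips byte-identically to the
emitted FASTA.

## Unplaced-scaffold filtering

The cascade runs in a fixed order, first matching rule wins:

1. **placed** — aligned fraction to the chromosome set ≥ 0.5 (evidence
   is supplied as a table; the threshold is configurable because
   upstream aligners differ);
2. **short** — length < 1 kb;
3. **contained** — canonical k-mer (k = 21) containment ≥ 0.95 in an
   already-kept longer sequence, greedy keep-longest. K-mer containment
   replaces all-by-all alignment: it is deterministic, dependency-free,
   and exact on the substring case the test suite checks;
4. **gappy** — N fraction **strictly greater than** 0.80; a sequence at
   exactly 80% N survives.

Survivors keep input order; the four category counts plus survivors sum
to the input count, and the filter is idempotent.

## Meta-assembly planning and the CE statistic

Meta-assembly merges are ordered (primary corrected by secondary), so
plans are ordered full binary trees: Catalan(n−1) × n! for n labels
(2 → 2, 3 → 12, 4 → 120), and 4! = 24 for the balanced two-step shape.
Candidate assemblies are ranked by largest maximum scaffold length,
then fewest scaffolds, then label — "longest scaffold" is read as the
single longest sequence, not total assembly span.

The CE statistic at position p is the z-score of the mean observed
size of inserts spanning p against the library model:
`CE(p) = (mean(sizes) − μ) / (σ/√n)`. The mean (not median) matches
the z-score form. Windows with fewer than `min_spanning` (default 5)
spanning inserts are reported as undefined (NaN) rather than zero,
since a zero would be indistinguishable from "no evidence of
distortion". Profile computation uses difference arrays over window
midpoints, O(inserts + windows), and is verified pointwise against a
direct spanning-set evaluation. Actual sequence merging (gap closing,
indel correction) is out of scope: plans and CE profiles are decision
support for an external merge tool.

## Evaluation

* **N50**: shortest sequence in the smallest length-sorted prefix
  reaching half the total; checked against a brute-force prefix search.
  Gap statistics count maximal N runs of ≥ 10 bases by default (a
  conventional floor; single Ns are usually ambiguity calls, not gaps).
* **AF spectrum**: variants join a population panel on exact
  (chrom, pos, ref, alt) — both sides must be normalized with the same
  convention. Histogram bins are right-closed on (0, 1] (width 0.05)
  so AF = 1.0 falls in the last bin; headline counts are reported at
  AF = 1.0, ≥ 0.99 and ≥ 0.90. Unmatched variants are counted
  separately and excluded from the histogram.
* **Callable regions**: a window is callable iff the fraction of
  samples with lo ≤ DP < hi (default 10 ≤ DP < 100) is ≥ 0.90 —
  the depth bound half-open (DP = 100 fails), the fraction inclusive
  (exactly 90% passes). Adjacent callable windows merge. Verified
  against a per-window double loop on 10⁴ × 20 random matrices.
* **Variant counting**: SNV iff both alleles are single bases;
  everything else (post-normalization) is an indel.

## Synthetic data

`synthfix` generates every input with ground truth attached:

* **Populations**: a random backbone (GC 0.41, human-like) plus H
  haplotypes. Carrier counts per site are assigned deterministically —
  the first k haplotypes carry the alternate — so voting outcomes are
  exact; a `sampled` mode draws carriers randomly for stochastic tests.
  Sites are specified in backbone coordinates, normalized at generation
  time, and rejected if their normalized REF spans collide (such truth
  sets would be ill-posed for voting). Haplotype sequences are built by
  direct right-to-left string editing, a code path independent of the
  consensus substitution engine, so byte-identical round trips between
  the two are a genuine cross-check.
* **Markers**: primer pairs written into non-overlapping loci with
  product sizes of 200–600 bp and per-map positions that increase
  monotonically with the locus coordinate, so all maps agree with the
  truth. Random 20-mer primers make spurious amplicons vanishingly
  unlikely at the 200-kb scales used.
* **Mate pairs**: noise-free mode emits inserts of exactly μ (so CE
  closed forms hold exactly); noisy mode draws normal(μ, σ). One
  structural edit (position, signed size) stretches or shrinks
  spanning inserts, emulating an assembly deletion or insertion.
* **Depth matrices**: depths clipped into [10, 100) so undropped
  windows are callable by construction; dropout windows force a
  configured fraction of samples below depth 10.

What this synthetic data does **not** emulate: repeats and segmental
duplications (the hard cases for e-PCR uniqueness and k-mer
containment), alignment and calling error in the input VCFs,
map-vs-map disagreement, GC-dependent coverage bias, and linkage
between sites. Passing tests therefore demonstrate correctness of the
decision rules and bookkeeping, not robustness to messy real inputs.

## Problem sizes and determinism

The test suite and the acceptance script run populations of 25–40 sites
on 30–60 kb backbones, 100 markers on 200 kb, 10-scaffold anchoring on
100 kb, and 10⁴-window depth matrices — sizes chosen so every check
runs in seconds while still exercising each rule's boundary cases
(half-open depth bounds, the exact-80% N rule, 3–3 ties). All
randomness flows from explicit seeds; per-site tie draws are keyed by
(seed, chrom, pos), so every pipeline output is reproducible
byte-for-byte under a fixed seed.

## Known limitations

* Voting assumes callsets share one backbone and one normalization
  convention; no cross-batch vote reconciliation is provided.
* Overlapping winning variants are resolved first-come (leftmost,
  then longest REF), which can drop a shorter nested winner that a
  haplotype-aware merge might have kept.
* The anchoring heuristic cannot split chimeric scaffolds at map
  conflicts; high-conflict scaffolds are simply left unplaced.
* k-mer containment can miss redundancy between highly diverged copies
  that alignment would detect, and conversely collapses exact repeats
  regardless of genomic context.
* CE uses a global σ; locally varying insert-size dispersion would
  distort the z-scores.
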