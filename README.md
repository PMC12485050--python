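# refforge

A toolkit for the bespoke computational stages of building a
**population-specific consensus reference genome** from a handful of
haploid assemblies — the situation faced when a few donors are deeply
sequenced and phase-resolved so that each contributes two haploid
assemblies, and the goal is a single reference that carries the
*population-major* allele at every site rather than any one donor's
private variants.

It is aimed at genome-assembly practitioners who already have
assemblies, variant callsets and marker/map tables in standard formats
(FASTA, VCF, BED, AGP, TSV) and need the glue stages between them:

| stage | module | what it does |
|---|---|---|
| majority consensus | `refforge.consensus` | normalize variants (left-aligned, parsimonious), vote across H haplotypes, substitute winners into the backbone, emit a liftover chain |
| electronic PCR | `refforge.epcr` | locate STS-marker amplicons from primer pairs + expected product sizes |
| map anchoring | `refforge.anchoring` | assign/order/orient scaffolds from genetic & radiation-hybrid maps, build pseudomolecules + AGP |
| unplaced filtering | `refforge.scaffold_filter` | placed → short → redundant → gap-dominated cascade |
| meta-assembly planning | `refforge.metaplan` | enumerate ordered merge plans, rank candidates, compute the CE statistic |
| evaluation | `refforge.evaluate` | N50/gap stats, AF spectrum vs a population panel, callable regions, variant counts |
| synthetic data | `refforge.synthfix` | seeded generators for every input above, with ground truth |

## The core rules

**Majority decision.** At a normalized variant site with allele counts
over H haploid assemblies, the backbone base is replaced by allele *a*
iff count(*a*) > H/2 (with H = 6: at least 4 of 6). When two or more
alleles tie for the maximum (e.g. 3–3), the winner is drawn uniformly
among the tied alleles by a generator keyed on (seed, chrom, pos), so
the draw is reproducible and independent of input order. This keeps
common alleles and drops private/rare ones.

**CE (compression–expansion) statistic.** For mate-pair inserts
spanning position *p* with library mean μ and SD σ:

```
CE(p) = (mean(observed insert sizes) − μ) / (σ / √n)
```

CE > 0 (inserts look stretched) flags sequence missing from the
assembly at *p*; CE < 0 flags inserted/expanded sequence. Windows with
fewer than `min_spanning` inserts are undefined, not zero.

**Ordered meta-assembly plans.** `x + y` merges primary `x` with
secondary `y`, so order matters: n assemblies admit Catalan(n−1) × n!
ordered full binary merge trees — 2, 12, 120 for n = 2, 3, 4, and 24
for n = 4 restricted to the balanced `((w+x)+(y+z))` shape.

## Worked example

Simulate a 6-haplotype population with 12 planted variant sites, build
the consensus, and inspect the decisions:

```
$ refforge simulate population --genome-length 8000 --n-sites 12 --seed 5 --out-dir pop
$ refforge consensus --backbone pop/backbone.fa \
      --calls pop/hap1.vcf,pop/hap2.vcf,pop/hap3.vcf,pop/hap4.vcf,pop/hap5.vcf,pop/hap6.vcf \
      --seed 1 --out-prefix jg
substituted 7 of 12 sites; skipped 0 overlapping winners
$ head -6 jg.decisions.tsv | cut -f1-7
chrom   pos     ref     counts          winner  substituted  tie
chr1    616     A       A:5,T:1         A       0            0
chr1    1231    T       T:4,TGC:2       T       0            0
chr1    1846    GTAT    G:3,GTAT:3      G       1            1
chr1    2462    T       G:4,T:2         G       1            0
```

Reading the rows: at chr1:616 only 1 of 6 haplotypes carries the
alternate, so the backbone allele A is retained; at chr1:2462 four of
six carry G, a strict majority, so G replaces T in the consensus; the
chr1:1846 site is a 3–3 tie between a 3-bp deletion and the backbone,
resolved by the seeded per-site draw (`tie` = 1). Seven of the twelve
sites had majority support and were substituted. The run also writes
`jg.consensus.fa`, a UCSC `jg.chain` liftover and a skip report.

Plan enumeration reproduces the combinatorics of merging three
assemblies:

```
$ refforge plans --labels jg1a,jg1b,jg1c | wc -l
12
```

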