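# Methods

## The detection problem

In an outbred F1 cross neither parent is inbred, so parental haplotypes
must first be reconstructed before meiotic recombination can be read out
of progeny genotypes.  `meiorec` consumes read-backed phasing output
(phase-set-annotated VCFs, or an equivalent block TSV) for two parents
and genotype VCFs for their progeny, and detects two classes of meiotic
event in each parental meiosis:

- **gene conversions (GC, non-crossovers)**: short tracts (20 bp to
  2 kb) copied non-reciprocally from one homolog to the other;
- **crossovers (CO)**: reciprocal exchanges, visible as a junction
  between two long (>10 kb) stretches inherited from different homologs.

## Pseudo-testcross sites and a/b labels

Only sites heterozygous in the focal parent and homozygous in the other
(segregation ab×aa for the maternal analysis, aa×ab for the paternal)
are informative: the homozygous parent can transmit only one allele, so
a progeny genotype reveals which allele the heterozygous parent passed
on.  At each such site the allele the other parent is homozygous for is
labelled **a** and the focal parent's alternative allele **b**; a
progeny genotyped `aa` inherited `a` from the focal parent and `ab`
inherited `b`.  A `bb` genotype is Mendelian-impossible and is treated
as missing (and counted).

### Site and block filters

Parental sites enter a haplotype block only with depth ≥ 5, ≥ 3 reads
per allele and genotype quality ≥ 60 (inclusive), and blocks must retain
at least 5 such sites.  Progeny genotypes are used only with depth ≥ 15,
genotype quality strictly > 60 and ≥ 5 reads on each called allele.  The
asymmetry (≥ 60 for parents, > 60 for progeny) is deliberate and follows
the method's original wording; with the bulk of genotype qualities far
from the boundary it has negligible numerical effect.

## Event classification

The inherited label sequence over a block is matched against the two
parental homolog label strings and segmented into maximal runs of
constant homolog.  Missing sites never terminate a run (continuity is
judged on informative sites only; an optional `max_gap_bp` can force
breaks, off by default).  Tract length is the span from the first to the
last SNP of the run, inclusive — a definition consistent with reporting
a 2–19 bp fragment bin, which a midpoint-based definition could not
produce.  The flanking opposite-state SNP positions are carried as
auxiliary `outer_start`/`outer_end` columns.

Each *interior* run (opposite-homolog neighbours on both sides) gets
exactly one class:

| condition | class |
|---|---|
| span < 20 bp or < 2 SNPs | `ignored_short` |
| 20 bp ≤ span < 2 kb and ≥ 2 SNPs | `gene_conversion` |
| otherwise (≥ 2 kb) | `ambiguous` |

Terminal runs are never conversion candidates (no flank on one side).
Independently, every junction between two adjacent runs *each spanning
more than 10 kb* is a crossover, localized to the interval between the
last SNP of the left run and the first SNP of the right run.  No minimum
flank length is required for a conversion call — only opposite-homolog
neighbours; the 10 kb requirement applies to crossovers alone.  Runs of
2–10 kb (and longer interior runs) are reported as `ambiguous` rather
than forced into either class.

Conversions and fragment classes are called within the short phased
blocks; crossovers are taken from the merged chromosome-scale haplotypes
(below) plus from short blocks lying outside every merged span — a block
occasionally spans more than 10 kb on its own.  Junctions inside a
merged span are visible to the merged unit, so taking them only once
avoids double-counting.

## Merging blocks with a linkage map

Phase sets are local: the homolog labelled "1" in one block bears no
relation to homolog 1 of the next.  Mapped markers carry a linkage phase
relative to the linkage group's reference homolog (standardized here as
per-marker `coupling`/`repulsion`: coupling means the marker's **b**
allele rides the reference homolog).  Each block containing mapped SNPs
is oriented so that merged homolog 1 carries **b** at coupling markers
and **a** at repulsion markers; blocks whose markers disagree are
resolved by majority vote, with ties excluded.  Oriented blocks are
concatenated in physical order.  Because orientation is decided per
block, the merge is associative.  Blocks with no mapped SNP cannot be
oriented and stay out of the merged haplotype (they remain usable as
short blocks); this matches the observation that chromosome-scale
haplotypes contain a small subset of all block SNPs.  The global
labelling of merged homolog 1 versus 2 is an arbitrary convention; all
downstream logic is invariant under a global swap.

## Segregation distortion and GC regions

Pseudo-testcross SNPs are expected to segregate 1:1.  For each SNP with
at least 100 genotyped individuals the statistic
`(n_aa − n)²/n + (n_ab − n)²/n`, `n = (n_aa + n_ab)/2`, is referred to a
χ² distribution with 1 degree of freedom (no continuity correction —
immaterial at these sample sizes; a flag enables it), and SNPs with
p < 0.01 are called distorted.  Gene-conversion tracts from all progeny
are reduced to a per-base multiplicity profile counting *distinct*
progeny (multiple tracts from one progeny count once, via per-progeny
flattening and a breakpoint sweep).  SNPs are stratified as GC5
(multiplicity ≥ 5), GC (≥ 1) or Non-GC.  The reported table counts the
GC row nested (GC5 ⊆ GC), matching the published presentation; an
exclusive partition table is emitted alongside.  Percentages are
rounded half-even to two decimals (84/99 → 84.85; mixed rounding in
print can differ by one unit in the last place).

## The simulator

`meiorec.simulate` generates the entire study design forward from a
seed: two outbred parents with a configurable segregation-type mix,
per-meiosis Poisson crossover and conversion counts, uniform breakpoint
and tract placement, read-level observation noise, and ground-truth
event tables.

Default study conditions: 2 chromosomes × 1 Mb; SNP density 10⁻³/bp
(positions sampled without replacement); segregation mix 0.4 ab×aa /
0.4 aa×ab / 0.2 ab×ab (the doubly heterozygous class is generated
precisely because the caller must ignore it); 10 progeny; mean depth
30× (Poisson); per-read miscall rate 0 (0.01 in the noisy scenario);
1 crossover and 20 conversion tracts per chromosome per meiosis, tract
lengths uniform on [50, 1500] bp; 5 % of each parent's pseudo-testcross
sites carry true-phase linkage-map entries; phase sets break between
adjacent heterozygous sites with probability 0.08, giving a mean block
of ~12.5 SNPs, the scale of read-backed phasing output on short-insert
libraries.

Genotypes are observed by splitting Poisson-depth reads binomially
between the two true alleles, flipping each read with the error rate,
and calling the maximum-likelihood diploid genotype; GQ is the
Phred-scaled likelihood ratio of the best to the second-best genotype
(capped at 99).  The formula is a stand-in for a caller's GQ and only
needs to be monotone in the strength of evidence so that the quality
thresholds bite.

Events are re-drawn until every pair (tract–tract, tract–breakpoint,
breakpoint–breakpoint) keeps at least `min_event_separation_bp`
(default 2000 bp, the conversion-length ceiling) of clearance.  Without
this the base-haplotype segment *between* two nearby events is itself a
short fragment flanked by opposite-homolog runs — indistinguishable
from a conversion by any length rule — and the ground-truth class of
the region would be ambiguous by construction.  This is a crude hard
floor, not an interference model; rates and length distributions are
unchanged.

### What the simulator does not emulate

Real data deviate in ways the simulator deliberately omits: phasing
switch errors inside blocks, reference/alignment artefacts and repeat
regions, depth that varies along the genome, non-uniform recombination
landscapes, crossover interference beyond the hard separation floor,
and tri-allelic sites.  Passing the recovery tests therefore shows the
*logic* of the chain (formats → blocks → labels → merge orientation →
segmentation → classification) is correct under the stated model; it
does not certify performance on real libraries.

## Recovery scoring

`recovery_compare` reports three quantities per event class:

- **sensitivity** over *eligible* truth events.  Eligibility is decided
  by classifying the **true** inherited homolog (from the simulator's
  gamete record) at exactly the informative sites the pipeline used: a
  truth tract is eligible when that information-optimal classification
  contains an overlapping conversion call (analogously for crossover
  intervals containing the breakpoint).  Ineligible events carry a
  diagnostic reason (too few SNPs in tract, sub-20 bp SNP span,
  genotype-filter losses, missing flank).
- **precision**: fraction of calls that overlap a truth tract (contain
  a truth breakpoint).
- **consistency**: fraction of calls identical to an
  information-optimal expected call.

With error-free reads the pipeline reproduces the expected call set
exactly (consistency 1), and all eligible truth events are recovered.
Truth-overlap precision, however, is bounded by SNP sparsity rather
than by the caller: a 2-SNP cluster of base-homolog sites lying between
two true tracts is, on the available information, a textbook conversion
signature, and a breakpoint adjacent to a tract with no informative
site between them shifts the apparent transition to the tract edge.
These are identifiability limits shared by any method using the same
rules (the distinction between a long conversion and a double crossover
is likewise out of scope).  At the default SNP density truth-overlap
conversion precision measures ≈ 0.85–1.0 depending on the random seed;
consistency stays at 1.0.

## Numerical and interface choices

- Internal coordinates are 1-based inclusive (VCF convention); BED
  output converts to 0-based half-open.
- An absent second-best alignment score is treated as −∞ (the read has
  no competing placement).  The alignment filter ships two score rules —
  `methods` (AS ≥ 60 and XS < AS, the default) and `results`
  (AS − XS ≥ 60) — because both variants are in circulation for this
  filter; the edit-distance condition (NM ≤ 8 % of read length) applies
  under either.
- Linkage-map ties in genetic position break by physical position;
  writers emit deterministically sorted, byte-stable output; the full
  simulate→call→score chain is reproducible from a single seed.
- Multi-allelic VCF records are dropped with a warning (the pipeline is
  strictly biallelic); indels are skipped.
- Test and acceptance simulations use the default desk-scale problem
  size (2 × 1 Mb, 10 progeny, ~2,000 SNPs per parent), which exercises
  every code path in a few seconds while leaving tract SNP coverage
  sparse enough that eligibility filtering is non-trivial.

## Known limitations

- Conversion tracts covering fewer than two informative SNPs (the large
  majority at realistic SNP densities) are invisible by design.
- Conversion calls between closely spaced true events, and crossover
  localization next to a conversion tract, can be mis-attributed (see
  recovery scoring above).
- The merged-haplotype view inherits any error in the input linkage
  map's phases; a wrongly phased marker that wins the majority vote
  flips a block and manufactures two spurious junctions at its edges.
- The distortion analysis tests each SNP at a fixed 1 % level with no
  multiplicity correction, mirroring the published procedure; it is a
  descriptive stratification, not a calibrated genome-wide test.
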