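# meiorec

Detection of meiotic **gene-conversion tracts** and **crossover
breakpoints** in outbred F1 populations, from phased parental SNP
haplotype blocks and progeny genotypes — with a forward meiosis
simulator so the whole chain is testable without sequencing data.

## Who this is for

Crossover rates drive linkage mapping, but gene conversions
(non-crossovers) are rarely measured in outbred species such as forest
trees, even though they skew allele transmission and can produce the
distorted markers that plague genetic maps.  `meiorec` implements a
block-based strategy for a two-parent F1 design (e.g. a *Populus*
full-sib family): it is aimed at researchers with whole-genome
sequencing of both parents and a modest number of progeny, plus existing
parental linkage maps.

## The method in brief

At a **pseudo-testcross** SNP — heterozygous in one parent, homozygous
in the other (segregation *ab*×*aa* or *aa*×*ab*) — every progeny
genotype reveals which allele the heterozygous parent transmitted.
Writing *a* for the allele the homozygous parent carries and *b* for the
alternative, a progeny genotyped `aa` inherited *a* and `ab` inherited
*b*.  Over a phased parental haplotype block this yields the inherited
haplotype, which is segmented into maximal runs matching one parental
homolog:

- an interior run of 20 bp–2 kb (SNP span) with ≥ 2 SNPs, flanked on
  both sides by the opposite homolog, is a **gene conversion**;
- a junction between two adjacent runs each spanning > 10 kb is a
  **crossover**, localized between the flanking SNPs;
- shorter runs are ignored, 2 kb–10 kb runs reported as ambiguous.

Blocks are merged into chromosome-scale haplotypes using linkage-map
phases (coupling/repulsion orient each mapped block), which is what
makes crossover detection possible.  Finally, population genotype counts
at pseudo-testcross SNPs are tested against 1:1 segregation with a
χ²₁ statistic, `(n_aa − n)²/n + (n_ab − n)²/n`, `n = (n_aa + n_ab)/2`,
and distortion rates are stratified by gene-conversion region coverage
(GC: ≥ 1 progeny; GC5: ≥ 5 distinct progeny).

Details, parameter defaults and known limitations: `docs/methods.md`.

## Worked example

Simulate a full study (two 1-Mb chromosomes, two outbred parents, ten
30× progeny) and run every stage on the generated files:

```sh
meiorec --log-level WARNING run-all --out-dir demo --seed 7 --min-typed 5
```

```
simulated 10 progeny on 2 chromosome(s); 849 truth events
P1: 64 blocks, 714 SNPs
P2: 46 blocks, 700 SNPs
Chr01: merged 12 blocks, 199 SNPs (18 mapped)
Chr02: merged 11 blocks, 154 SNPs (14 mapped)
P1: 6 gene conversions, 21 crossovers
...
P2: 14 gene conversions, 12 crossovers
```

The maternal (P1) analysis found 64 usable haplotype blocks (714
pseudo-testcross SNPs after the depth/quality filters), merged the
mapped ones into one chromosome-scale haplotype per linkage group, and
called 6 conversion tracts and 21 crossovers across the ten progeny.
Most of the 849 simulated truth events are invisible by design: at one
SNP per kb the median conversion tract covers no informative marker at
all, which is exactly the regime the eligibility accounting below makes
explicit.  `demo/` now contains the events BED, per-length-bin and
per-progeny tables, block-sharing counts, and the distortion table
(`--min-typed 5` lowers the population floor so ten progeny pass; on
real population data keep the default of 100).

The same chain is available in memory, with ground-truth scoring:

```python
from meiorec import (SimulationConfig, simulate_dataset, analyze_dataset,
                     recovery_compare)

ds = simulate_dataset(SimulationConfig(seed=1))
res = analyze_dataset(ds)
rc = recovery_compare(res.events, ds.truth, res.expected_events,
                      res.informative_sites, res.pt_site_positions)
print(f"eligible GC tracts recovered: {rc['gc']['n_recovered']}/{rc['gc']['n_eligible']}")
print(f"crossovers recovered:         {rc['co']['n_recovered']}/{rc['co']['n_eligible']}")
print(f"GC call consistency:          {rc['gc']['consistency']:.2f}")
```

```
eligible GC tracts recovered: 25/25
crossovers recovered:         24/24
GC call consistency:          1.00
```

Every truth event that covers at least two well-genotyped informative
SNPs with the required flanks is recovered, and each call coincides
exactly with the classification of the true inherited labels.

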