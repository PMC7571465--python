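# rilmap

Bin-marker genotyping, high-density linkage-map construction and inclusive
composite interval mapping (ICIM) for recombinant inbred line (RIL)
populations, with a ground-truthed single-seed-descent population simulator
and leaflet-shape morphometrics.

## The problem

Genome-sequenced biparental RIL populations (here modelled on a mung bean,
*Vigna radiata*, cross segregating for lobed and indented leaflets) yield
hundreds of thousands of SNP calls at modest coverage. Turning them into a
genetic map and QTL calls takes a chain of standard but fiddly steps, each
with thresholds that matter:

1. **Bin genotyping** — keep only SNPs where the parents are homozygous for
   different alleles (the aa × bb pattern); blank calls below 4 reads; drop
   lines with more than 2% heterozygous calls (contamination in a selfed
   RIL); smooth each line with a 15-SNP sliding window (a window is typed
   `aa`/`bb` when more than 11 of its SNPs agree, otherwise `ab`); merge
   adjacent SNPs with identical genotype vectors into *bin markers*; keep
   bins longer than 10 kb whose aa:bb ratio passes the 1:1 χ² test at
   α = 0.01.
2. **Map construction** — group bins by reference chromosome, estimate
   pairwise recombination (RIL-observed fraction *R* inverted to meiotic
   *r* via the Haldane–Waddington relation `R = 2r/(1+2r)`), order each
   group by nearest-neighbour + two-opt minimisation of SARF (the sum of
   adjacent recombination fractions) with a 5-marker exhaustive ripple, and
   place markers with Kosambi's function `d = 25·ln((1+2r)/(1−2r))` cM.
3. **Leaf morphometrics** — the lobed-leaflet indices
   `R = 100·V/(V + lobed area)` and `Q = 100·L1/L2`, the apex count NA for
   indented leaflets, and the 1:1 segregation χ² test.
4. **QTL scanning** — additive ICIM: stepwise cofactor selection
   (entry p < 0.001), a 0.1-cM interval scan of the cofactor-adjusted
   phenotype with an EM-fitted two-class normal mixture,
   `LOD = log10(L1/L0)`, and a 1000-permutation genome-wide threshold at
   P = 0.05.

Real read data are not required: `rilmap.simulate` breeds F₁ → RIL₈
populations by strict single seed descent with Poisson crossovers, observes
them through a depth/error model, injects QTL at a chosen percentage of
variance explained (PVE), and draws parametric leaf outlines with exact
analytic areas — so every stage can be validated against known truth.

## Worked example

Simulate 175 RIL₈ lines on three 90-cM chromosomes with one QTL for the
leaf area ratio R (40% PVE at 43 cM on the second chromosome), then scan:

```python
import numpy as np
from rilmap import (SimConfig, QTLSpec, breed_ril_population,
                    simulate_phenotypes, truth_bins_and_map,
                    ScanParams, scan_trait)

cfg = SimConfig(
    n_chromosomes=3, chrom_lengths_cM=[90.0] * 3,
    chrom_lengths_bp=[20_000_000] * 3, n_snps_per_chrom=30, n_lines=175,
    qtl_specs=[QTLSpec(chromosome=1, position_cM=43.0, additive_effect=1.0,
                       target_pve=40.0, trait="R")],
    seed=7,
)
pop = breed_ril_population(cfg)
pheno = simulate_phenotypes(pop, cfg.qtl_specs, np.random.default_rng(8))
binset, gmap = truth_bins_and_map(pop)
profile, threshold, qtl = scan_trait(
    gmap, binset, pheno["R"].to_numpy(),
    ScanParams(step_cM=0.5, n_permutations=200, seed=9), trait="R",
)
print(f"permutation LOD threshold (alpha=0.05): {threshold:.2f}")
for q in qtl:
    print(f"{q.name}: {q.lg} @ {q.peak_cM:.1f} cM  LOD={q.lod:.1f}  "
          f"PVE={q.pve:.1f}%  additive={q.additive:.2f}  "
          f"flanked by {q.left_marker}/{q.right_marker}")
```

prints

```
permutation LOD threshold (alpha=0.05): 2.47
qR.1: LG2 @ 42.4 cM  LOD=16.7  PVE=35.4%  additive=0.93  flanked by bin01_0014/bin01_0015
```

— the injected QTL is recovered 0.6 cM from its true position, with the
estimated PVE and additive effect close to the simulated 40% and 1.0 (PVE
estimates at a detected peak are mildly conservative at this sample size),
and the scan's genome-wide significance threshold comes from its own
permutation test.

The same stages are available from the shell
(`rilmap simulate|genotype|map|leaf|qtl|run`), reading and writing VCF and
TSV; `rilmap run --config cfg.json --seed 7 --out outdir` executes the
whole pipeline and is byte-reproducible for a given config and seed.

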