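# Methods

This note records the models behind each stage, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
establish about behaviour on real data.

## Population model

Lines descend from an F₁ between two fully inbred parents by strict single
seed descent: one plant per line selfed once per generation, no selection
or mortality, to generation 8 by default (F₁ = generation 1). Meiosis
places a Poisson number of crossovers per chromosome with mean
`length_cM/100` and uniform positions — no interference (Haldane model).
Interference was left out deliberately: the downstream distance scale uses
Kosambi's function, which *assumes* partial interference, so the pipeline
is evaluated under a mild model mismatch of exactly the kind real data
present (see "Known biases" below). Per-locus heterozygosity halves each
generation, `0.5^(t-1)` at generation *t* (0.78% at RIL₈); this is a tested
invariant.

Residual heterozygosity is *tract-structured*, not i.i.d.: a line either
carries a surviving het tract (cM-scale) or none. The per-line het
fraction is therefore long-tailed — about 10% of honest RIL₈ lines exceed
2% het calls even without any contamination (measured at n = 1000 lines).
Consequently the 2% "abnormal line" filter removes contaminated lines
*plus* the natural het tail; with 15/190 lines contaminated at a 5%
forced-het rate, all 15 are always removed (their het fraction is ~5.7%)
along with a seed-dependent handful of tail lines. We regard this as a
property of the filter worth knowing, not a defect: a 2%-of-calls het
excess is indistinguishable in kind from a large unfixed tract.

## Observation model

Read depth per call is Poisson(`mean_depth`); each read draws one of the
genotype's two alleles and is miscalled with probability `error_rate`. The
emitted genotype is the maximum-likelihood call from the (ref, alt) read
counts — the behaviour of a standard variant caller. Two consequences the
genotyper depends on: an isolated miscalled read does not flip a
homozygote (two concordant errors are needed, probability ~`(D·e)²/2`),
and a true heterozygote whose sampled reads cover only one allele
collapses to that homozygote — the realistic failure mode that motivates
the depth-4 floor. Calls are emitted on a random REF/ALT orientation per
SNP so that parental re-coding is genuinely exercised. Contaminated lines
have each call replaced by a heterozygote with probability
`contamination_het_rate` (default 5%) before observation, emulating
uniform foreign-DNA admixture.

SNP placement: one SNP per `length_bp/n` window, jittered uniformly by
`marker_jitter` (default 0.45) of the spacing. Benchmarks of marker
*ordering* use `marker_jitter = 0`: with jitter, adjacent gaps can fall
below 0.5 cM, where 200 lines carry on the order of one recombinant
between the pair and no pairwise method can order them — a regular grid
keeps the benchmark about the algorithm rather than about
non-identifiability.

## Bin genotyping

Window typing follows the strict-majority rule: a 15-SNP window is `aa`
when more than 11 of its calls are `aa`, `bb` when more than 11 are `bb`,
else `ab`. The rule is applied symmetrically to both homozygote classes;
missing calls count toward neither threshold, and the threshold stays
absolute (not proportional to the non-missing count). Window types map to
SNPs by the centre-SNP convention, the first and last ⌊15/2⌋ SNPs taking
the nearest full window's type; a chromosome shorter than one window is a
single window. Smoothing implies a known artefact: a clean crossover
becomes an `aa → ab → bb` transition roughly eight SNPs wide, so smoothed
calls disagree with truth in a fixed number of SNPs per crossover.
Agreement with truth therefore improves with marker density — ≥99% at
2000 SNPs per 100 cM chromosome (tested), far lower at 10× sparser
spacing. Conclusions about smoothing accuracy transfer to real data only
at comparable density; the motivating study had ~21,500 aa × bb SNPs.

Bins are maximal runs of adjacent SNPs with identical genotype vectors
across all lines. Spans are 1-based inclusive; "longer than 10 kb" is
strict (`end − start + 1 > 10000`). The 1:1 segregation test is
`χ² = (aa − bb)²/(aa + bb)` at 1 df with no continuity correction. Every
filter emits a machine-readable removal table, and input = kept + removed
is enforced by construction.

## Recombination fractions and distances

The observed recombinant fraction between two bins uses gamete
accounting: opposite homozygotes count 1, a homozygote against a
heterozygote counts ½ (the het call carries exactly one recombinant
haplotype), het–het counts 0, and lines missing at either bin are
excluded; pairs with fewer than 20 informative lines are uninformative
(r = 0.5, LOD 0). The half-weight rule matters: window smoothing renders
*every* crossover as a short het blur, so with opposite-homozygote
counting alone every adjacent-bin recombination fraction would be zero
and the adjacent-pair map would collapse to 0 cM (we observed exactly
this). Two half-steps across a blur sum to the one-crossover step in the
linear regime, restoring additivity.

The RIL-observed fraction *R* is inverted to the meiotic fraction by the
fixed-population Haldane–Waddington relation `r = R/(2(1−R))`, then placed
on the map with Kosambi's function. Distances accumulate over adjacent
pairs only; multipoint likelihood is out of scope. Adjacent *r* above
0.49 is capped (and logged) before the Kosambi transform.

Ordering minimises SARF: a nearest-neighbour seed grown from the
smallest-r pair (lowest indices on ties), two-opt segment reversals to a
local optimum, then rippling — every 5-marker window tested against all
120 permutations, accepting only strict improvements, repeated until a
full pass changes nothing. All tie-breaks are index-based, so ordering is
deterministic. Against brute-force enumeration of all 8-marker orders the
combination attains the global SARF optimum in 100/100 map-like matrices.
Groups are preset by reference chromosome; the LOD ≥ 3 linkage check is
diagnostic only (violations reported, never re-assigned). Each assembled
group is oriented so the first marker has the smaller bp position.

The summary table reports, per group, the average spacing as
`length/(markers − 1)`, and overall both conventions —
`total/markers` and `total/(markers − groups)` — since published summary
tables mix the two.

### Known biases

On Haldane-simulated truth the estimated group length is ~6.5% short at
3.3 cM marker spacing: Kosambi-on-Haldane contributes about −3.2% per
gap, and applying the fixed-population (F∞) Haldane–Waddington transform
to a finite F₈ population the remainder. The per-group length SD at
n = 200 lines is ~6 cM per 100 cM — the two-point information limit. Both
are properties of the prescribed method, not estimation bugs; recovery
tests therefore check the *median* length error against the 15% band.

## Leaf morphometrics

Shapes are ellipse-based outlines in arbitrary units with the main vein
as the long axis (ratios are scale-free): indented leaves superimpose
`n_apexes` radial bumps on a rounder ellipse; lobed leaves cut a wedge
notch at `notch_position` of the vein on both sides, its vertex pulled
`lobe_depth` of the way from the margin chord toward the vein. Analytic
V, lobed area, L1 and L2 are stored with each shape and agree with the
polygon-measured values to ≤0.01% at the default 256 vertices.

Measurement conventions: V is the shoelace area. Lobed areas use *chord
closure of annotated concave pairs* — each notch is the convex-hull
pocket containing an annotated concave vertex; filtering pockets by
annotation keeps the convex tip/base and any apex bumps from inflating
the denominator of R. When several pairs exist, the deepest (largest
pocket area) defines L1 via its chord's intersection with the base→tip
segment; a chord that misses the vein is an error naming the pair. With
no concave pairs, L1 = L2 by convention (Q = 100 for unlobed leaves).
Apex counting prefers the annotated set; otherwise apexes are strict
circular local maxima of centroid distance with prominence ≥1% of L2,
suppressing discretisation ripple. Lines classified `mixed` (both lobed
and indented) are excluded from QTL input.

## ICIM QTL scanning

Markers are coded +1/−1/0 (aa/bb/het-or-missing). Cofactors come from
forward-backward stepwise regression: entry at partial-F p < `pin`
(default 0.001), removal at drop-one p > `pout` (default 2·pin, the entry
probability being the only one published), smallest-p-first with index
tie-breaks, capped at min(n−2, markers, 50) terms.

The scan grid covers each group end-to-end at `step_cM` (default 0.1)
*plus every marker position*, so marker-coincident positions use observed
genotypes exactly; there the mixture collapses to two-class regression
and reproduces the single-marker regression LOD to 1e−6 (tested). At each
position the phenotype is adjusted by subtracting all cofactor
contributions except those of the current interval's flanking markers
(released, at their fitted coefficients). Each line's prior probability
of the `aa` class comes from its nearest *informative* (homozygous)
flanking markers: inverse-Kosambi distances, transformed to RIL scale,
combined under a Markov assumption along the chromosome; lines lacking a
flank on one side condition on the other alone, and on neither get 0.5.
The two-component equal-variance normal mixture is fitted by EM (≤50
iterations), initialised from prior-weighted class means; convergence is
declared on the LOD itself (|ΔLOD| ≤ 1e−8), which makes the stopping rule
invariant to phenotype shift and scale, and the reported LOD is clipped
at 0. The additive effect is half the fitted class-mean difference; PVE
is `100·Var(π·μ₁ + (1−π)·μ₂)/Var(y)` against the *raw* phenotype
variance. PVE at a detected peak is mildly conservative (a few points
below target at PVE 40, n = 175) because fitted class means shrink under
noise.

Permutation thresholds shuffle the phenotype against the genotypes,
re-run the *entire* analysis including stepwise selection, and take the
`⌈(1−α)N⌉`-th smallest genome-wide maximum LOD. Under exchangeability the
exceedance probability of a fresh null scan is `(N−⌈(1−α)N⌉+1)/(N+1) ≈ α`;
the null-calibration test confirms the empirical rate falls inside the
central 95% of Binomial(50, 0.05). Permuted scans run vectorised (one EM
per position across all permutations), which is what keeps a
200-permutation threshold at a few seconds per trait.

QTL are contiguous supra-threshold runs, reported at the run's peak with
the nearest mapped bins on each side, their physical bp span, and both a
flanking-bin interval and a 1.5-LOD-drop support interval (the field uses
both conventions; neither is asserted as "the" interval). Traits (NA, R,
Q) are scanned independently; dominance and epistasis are out of scope
(RILs are essentially homozygous).

## Phenotype simulation

Each QTL adds `+a`/0/`−a` for aa/ab/bb at its true genetic position
(evaluated on the haplotype mosaics, not the nearest marker). Per trait,
noise variance is set from the realised genetic variance so the summed
target PVE holds in-sample: `σ² = Var(g)·(100 − ΣPVE)/ΣPVE`; with
multiple QTL, per-QTL PVEs are exact only when the stated effects are
mutually consistent with them. Trait baselines (NA 6, R 75%, Q 70%) and
the no-QTL noise SDs (1.5, 8, 8) are desk-scale conventions chosen to
keep values in plausible ranges; NA is rounded and floored at 0.

## Problem sizes used in tests

Recovery and calibration experiments run at deliberately scaled sizes
chosen as the package's own benchmark design: 3 chromosomes × 30 bins ×
175–200 lines for map and QTL recovery (20 replicates each), 2 × 20 × 100
for null calibration (50 scans × 200 permutations), 300–2000 SNPs per
chromosome for genotyping checks. These preserve the statistical structure
(marker density per cM, lines, PVE) that the conclusions depend on.

## Limitations

* No crossover interference in the generator, while distances assume
  Kosambi — the resulting ~6% length compression is quantified above.
* The contamination model (uniform het inflation) is one of several
  mechanisms that produce "abnormal" calls; the 2% filter does not
  distinguish it from natural unfixed tracts.
* Adjacent-pair distances, not multipoint likelihood; ordering quality at
  sub-cM gaps is information-limited for any pairwise method.
* Leaf outlines are a parametric family: landmarks arrive annotated, so
  the measurement code's landmark *detection* is exercised only for
  apexes, not for concave pairs; image segmentation is out of scope.
* Phenotype noise is Gaussian and environment-free; multi-environment
  scans are modelled as separate traits, not jointly.
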