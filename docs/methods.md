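# Methods

This note documents the models, algorithms and numerical choices behind
`crosshap`, and what the simulation-based tests do and do not establish.

## Study design being modelled

An outcrossing F1 ("pseudo-testcross") population: two highly heterozygous
parents, ~100 progeny, genotyped by low-coverage (skim, ~5x) whole-genome
sequencing against a chromosome-scale assembly. Only SNPs heterozygous in
exactly one parent carry linkage information; at such a SNP the homozygous
parent's allele is obligate in every offspring, so subtracting it reveals the
allele — hence the haplotype — transmitted by the informative parent. Marker
order is taken from assembly coordinates (1-based bp); no de novo map-order
estimation is attempted, and genetic distances (cM) are used only inside the
simulator.

## Simulator (`popsim`)

* **Marker map.** Per linkage group, `markers_per_lg` positions are drawn
  uniformly without replacement on `[1, lg_length_bp]`; the cM coordinate is
  proportional to bp (a uniform recombination landscape). Defaults: 20 LGs,
  16 Mb and 60 cM each, 104 progeny, class fractions 0.4 / 0.4 / 0.1
  (maternal-informative / paternal-informative / both-het), 1% genotype
  error, 10% missing calls. The 200 SNPs/LG default is a desk-scale stand-in
  for the millions of skim-called SNPs in real data; all statistical
  structure (1:1 segregation, linkage decay, error/missingness) is preserved,
  only the marker density is reduced, which coarsens breakpoint resolution.
* **Meiosis.** Crossover counts are Poisson with mean `lg_length_cm/100` and
  positions uniform on the cM axis — the Haldane model, i.e. no interference.
  Interference would only sharpen the spacing of double crossovers, which
  none of the tested inferences depend on.
* **Errors.** A genotyping error flips one allele of a call to a uniformly
  chosen different base (mimicking a low-coverage miscall without modelling
  reads); missingness is applied after error. Parents are corrupted by the
  same process as progeny — they are genotyped on the same platform — which
  matters: a parent-level error can masquerade as an informative marker (see
  anchoring, below).
* **Trait.** `trait = baseline + Σ_q effect_q[diplotype at q] + N(0, σ)`.
  The default single-QTL effect table is
  `{M1P1: −56, M1P2: +84, M2P1: −71, M2P2: +99}` g around a 400 g baseline
  with σ = 80 g: near-additive and paternal-dominated (the paternal contrast
  is 170 g, attenuated to 140 g in the alternative maternal background;
  the maternal marginal effect is 0), matching the effect structure observed
  for mango fruit weight, where one parent's haplotype carries the major
  effect and group means are close to additive. The extreme group means sit
  at ~329 g and ~499 g. An individual that recombines around a QTL still has
  a well-defined haplotype pair at the QTL position itself, which is what
  receives the effect.
* **Determinism.** One master seed; stage streams are spawned via
  `numpy.random.SeedSequence`, and repeated runs are byte-identical.

The simulator does **not** model read depth, reference bias, segregation
distortion, clustered recombination, epistasis, or genotype-by-environment
variance. Passing recovery tests therefore certify the inference algorithms
under the stated error model, not performance on any particular real dataset.

## Phasing (`phasing`)

Transmission at an informative marker is allele-level (obligate-allele
subtraction; Mendelian-inconsistent calls are flagged and left unknown).
Phasing then chooses, per marker, an orientation bit mapping the two parental
alleles onto haplotype labels 1/2:

* **Greedy chain.** Marker 1 is oriented arbitrarily; each subsequent marker
  is oriented to agree with the previous oriented marker in the majority of
  progeny informative for both. Because total recombinations decompose over
  adjacent marker pairs and each pair's relative orientation is free, the
  greedy choice attains the exhaustive minimal-recombination optimum on
  complete data (verified against an oracle that enumerates all 2^(m−1)
  orientations). Labels within a linkage group are defined only up to a
  global 1↔2 flip; every downstream statistic is invariant under that flip.
* **Noise-marker anchoring.** A both-het or uninformative SNP whose parent
  call was misread looks informative but transmits random or constant labels.
  If such a marker anchors the chain, every downstream marker inherits a
  random orientation — one corrupted SNP can make the whole population appear
  to recombine at a single point. A marker's incoming vote is therefore
  declared indecisive when it rests on ≥ 25 pairs yet its margin is within 3
  binomial standard deviations of an even split; indecisive markers are
  flagged low-confidence and skipped as anchors (after three consecutive
  skips the chain re-bases so a corrupt leading marker cannot stall it).
  Below 25 pairs the test has no power and behaviour reduces to plain greedy,
  preserving the oracle equivalence on small instances.
* **Breakpoints.** Labels are run-length smoothed: runs shorter than
  `min_run` (default 3; rationale: isolated miscalls at skim coverage) are
  masked to unknown, measured on the subsequence of non-unknown entries.
  Each remaining label switch is reported as the bp interval between the
  flanking informative markers — never a point estimate, since that is the
  resolution limit of the data.

**Detectability.** A crossover produces no observable switch when it falls
outside the parent's informative-marker span or when an even number of
crossovers lands in the same inter-marker gap. Recovery is therefore scored
against *detectable* crossovers (odd parity within a gap inside the span):
on clean data every detectable crossover is recovered exactly and no spurious
breakpoints are called. Smoothing additionally hides switches within
`min_run − 1` markers of a linkage-group end, so with `min_run = 3` about
`4/M` of crossovers are lost on an M-informative-marker group; at ~200
informative markers per parent per group and 1% error, ≥ 95% (measured
~97%) of detectable crossovers are recovered within one flanking-marker
interval.

## Association (`association`)

Simple linear regression of the trait on a per-marker 0/1
transmitted-haplotype indicator (two scans, maternal and paternal — the
informative marker sets are disjoint), individuals with unknown transmission
dropped marker-wise; allele-dosage coding is available for unphased input.
The asymptotic p comes from the Wald t with n−2 df. The permutation p
shuffles predictor labels and uses the add-one convention
`p = (1 + #{|t*| ≥ |t|})/(n_perm + 1)` (never zero; two-sided). Since
permuting the trait leaves its mean and variance unchanged, |t| is monotone
in the absolute centred cross-product, so each marker's permutation null
costs a single matrix–vector product. Exact enumeration over all n! orders
is provided for small n. Degenerate inputs (constant trait or predictor,
n < 3) return p = 1 with a flag rather than failing.

Regions merge markers with permutation p ≤ 0.001 (the study's threshold;
no family-wise correction is applied, mirroring the original analysis — a
Bonferroni count is trivial to add downstream) while consecutive significant
SNPs are ≤ `max_gap_bp` apart (default 1 Mb, configurable and logged in the
run manifest). Region bounds are the min/max bp of member SNPs. Note a
density interaction: at desk-scale simulation density (~220 kb between
informative SNPs) the probability that a given position falls inside a
> 1 Mb gap of the significant set is ~5%, so threshold-and-merge regions
occasionally split around the causal position; at real skim densities
(~100 bp spacing) the 1 Mb default is conservative. Default permutation
count is 9 999 (10× the reciprocal threshold); simulation experiments in the
tests use 1 999 to stay within desk-scale runtimes.

## Diplotypes (`diplotypes`)

Per region and parent, the non-unknown smoothed labels at the parent's
in-region informative markers reduce to: both labels observed → RECOMBINANT
(strict uniqueness — any sustained second haplotype counts as an in-region
recombination event); fewer than `min_info_frac` (default 0.5) of the
parent's region markers called → UNKNOWN; otherwise the unique label. The
same `min_run` smoothing as breakpoint calling is applied first so a single
miscalled SNP does not flag a recombination. RECOMBINANT and UNKNOWN
individuals are excluded from, but reported alongside, the effect test.

The effect test is classical one-way fixed-effects ANOVA (explicit
sum-of-squares decomposition with closed-form handling of the degenerate
cases SSB = 0 → F = 0, p = 1 and SSW = 0 → F = ∞, p = 0), with Tukey HSD
pairwise p-values from the studentized range (scipy); with exactly two
groups the Tukey adjusted p equals the ANOVA p. Groups need ≥ 2 members;
with fewer than two usable groups the report carries null test fields and a
reason. A Welch heteroscedastic variant is available behind a flag; the
default assumes homoscedastic Gaussian groups as the classical analysis
does. Diplotype labels render with user prefixes (e.g. TA/KP → TA2KP1).

Panel prediction re-calls diplotypes from a marker subset with `min_run = 2`
(an isolated flip on a small panel would otherwise masquerade as in-region
recombination) and scores agreement against full-region calls over
individuals with a proper four-class full call.

## Candidate genes (`annotation`)

1-based closed-interval queries. The default membership rule is
gene-start-in-region because published gene tables often list a single bp
position per gene; an overlap rule covers full GFF3 input (via gffutils, with
an optional seqid→LG mapping). The packaged mango fruit-weight reference
(gene table plus LG4/LG7 region bounds for the 'Tommy Atkins' ×
'Kensington Pride' population) is curated from published results: 28 LG4
genes and 7 LG7 genes, every position inside its region's bounds.

## Pipeline (`pipeline`, CLI, `analysis/`)

Flat YAML configuration with unknown-key rejection; all parameters, package
version, seeds and per-stage record counts are echoed to `manifest.json`
(no timestamps, so fixed config + seed gives byte-identical output trees).
Stage failures raise a typed error naming the stage. The `analysis/` scripts
present the same stages as a numbered narrative over `results/`.

## Problem sizes used in tests

Chosen to exercise each claim at the smallest scale that measures it:
exact-recovery checks use 5 LGs × 200 SNPs × 100 progeny (zero error);
noisy breakpoint recovery uses ~200 informative SNPs per parent per LG over
three seeds; null calibration uses 1 000 replicates at 199 permutations
(resolution 0.005 at α = 0.05); QTL + diplotype-effect recovery uses 100
replicates of a 2-LG × 200-SNP, 104-progeny population at 1 999 permutations.

## Known limitations

* Greedy phasing is oracle-equal on complete data; with missing data the
  adjacent-pair objective and the consecutive-non-missing recombination count
  can differ, and the greedy result is then only near-optimal.
* Breakpoints near linkage-group ends (within `min_run − 1` informative
  markers) are invisible after smoothing; even numbers of crossovers in one
  inter-marker gap are invisible in principle.
* Single-marker association ignores kinship and multi-QTL interference;
  interval mapping and mixed models are out of scope.
* Region bounds stop at the outermost significant SNP; the causal position
  can fall just outside when significant markers are sparse.
* The recombinant-exclusion rule is strict uniqueness after smoothing; with
  very wide regions a large fraction of individuals is genuinely recombinant
  and excluded, shrinking the effect-test sample.
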