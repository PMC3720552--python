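# Methods

This note documents the models, conventions and numerical choices behind
`equicnv`, and what the synthetic-data generator does and does not emulate.

## Coordinates and interval algebra

All genomic intervals are 1-based inclusive (`size = end − start + 1`), the
convention of Illumina array reports and of PennCNV/QuantiSNP output; BED
input/output is converted at the boundary (`bed_start = start − 1`,
`bed_end = end`). Adjacent intervals (`[100,200]`, `[201,300]`) do **not**
overlap.

A CNV region (CNVR) is a connected component of the call-overlap graph.
Two calls are linked when they satisfy the `OverlapSpec`: `any` (≥ 1 shared
bp, the default) or `reciprocal` (the shared length is at least fraction
*f* of *each* call). The component search is a per-chromosome sweep over
start-sorted calls with union-find; only physically overlapping pairs are
tested, which is sound because any reciprocal criterion implies
any-overlap. A region's envelope is the union span (min start, max end) of
its members.

Note a deliberate non-property: tightening the overlap criterion does not
monotonically shrink *consensus* counts. A stricter criterion can split one
component into several, each of which may separately retain support from
all three callers. Monotonicity holds at the pair level (a pair satisfying
a stricter reciprocal fraction satisfies every looser one) and for pairwise
hit fractions, and that is what the property tests assert.

## Quality control

Samples are kept when call rate **>** 0.90 (strict, matching the usual
"call rate > 90 %" phrasing) and SD(LRR) ≤ 0.3 and |GCWF| ≤ 0.02
(boundary-inclusive for keeping). Calls are kept when they span ≥ 3 probes;
QuantiSNP calls additionally require Log Bayes Factor ≥ 10 and CNVPartition
calls confidence ≥ 35. Missing per-sample metrics skip the corresponding
rule (logged) rather than excluding the sample. The SD(LRR)/GCWF rules are
applied to all callers' samples uniformly; per-caller application would be
a one-line change but there is no evidence the thresholds should differ.
CNVPartition's internal minimum-homozygous-region parameter is a
caller-side setting and is not re-applied as a filter. Diploid (cn = 2)
rows in input call tables are dropped with a counter, not an error, so
merged exports can be ingested.

## Consensus levels

A locus (pooled-call component) is a consensus CNV when every caller
contributed ≥ 1 supporting call, resolved at three stringencies:
**population** (support anywhere), **breed** (all three callers within at
least one common breed; one record per qualifying locus × breed), and
**individual** (all three callers in at least one common animal; one
record per locus × animal). Record counts at the finer levels can
therefore exceed the population count, but *distinct loci* are monotone:
individual ⊆ breed ⊆ population. A consensus is classified `loss` when
every supporting call has cn < 2, `gain` when every call has cn > 2, and
`both` otherwise.

## Enrichment

The per-chromosome statistic is SNP-count based: markers covered by CNVRs
divided by chromosome length, flagged enriched when strictly above the
genome-wide density (total covered markers / total autosome length). The
bp-coverage percentage is reported alongside because it is the more
familiar summary, but the flag follows the SNP-density rule; at exact
equality (e.g. a single-chromosome genome) nothing is enriched. The
optional permutation test preserves the observed region lengths, assigns
chromosomes with probability proportional to length among chromosomes the
region fits on, draws starts uniformly, and counts **distinct** covered
markers per placement (overlapping placements are not double-counted, for
comparability with the merged observed regions). p-values are add-one
corrected: `p = (1 + #exceedances) / (n_perm + 1)`.

## Association model

Per region, OLS of height on copy-number dosage with breed fixed effects.
Breeds are the stratification axis in horse cohorts; with no
variance-component information available to fit a mixed model, breed fixed
effects plus *within-breed* permutation is the design that exactly
preserves each breed's trait distribution under the null. The fit is
computed by within-breed projection: dosage and trait are demeaned within
breed, after which the breed-adjusted t statistic is the simple-regression
t on residuals with `df = n − n_breeds − 1` — algebraically identical to
OLS with a full breed-indicator design (verified against statsmodels in
the tests) and cheap enough to re-evaluate for every permutation as one
matrix product. Family-wise p-values use the max-|t| statistic per
permutation, genome-wide over all tested regions and chromosome-wide over
the region's chromosome.

Copy number is coded as numeric dosage 0–4 (gains capped at 4); a
`loss` carrier coding (1 if cn < 2) is available since deletion loci are
the usual association targets. Under dosage coding a deletion allele that
increases the trait yields a **negative** coefficient; the results table
adds an explicit direction label to avoid sign confusion. Regions with
fewer than `min_carriers` (default 5) non-diploid animals, or with no
dosage variance after projection, are skipped and logged. Genotypes at a
region default to 2; where several calls overlap, the minimum copy number
wins (a homozygous deletion trumps a heterozygous one). Degenerate inputs
error early: fewer than 30 phenotyped animals, or a zero-variance trait.
Single-animal breeds contribute nothing after demeaning and trigger a
warning.

## qPCR

Replicate Ct values are averaged per (sample, assay); ΔCt is target minus
reference (GAPDH by default), ΔΔCt compares to a diploid calibrator, and
`rq = 2^−ΔΔCt` assuming amplification efficiency exactly 2. Theoretical rq
levels against a two-copy calibrator are k/2 for k copies; classification
uses the midpoint bin edges 0.25 / 0.75 / 1.25, with rq ≥ 1.75 reported as
copy number 3 plus an out-of-range flag. Concordance is computed
per-(sample, region): per-caller accuracy (caller cn equals qPCR cn, with
2 where the caller made no call), false-negative rate (qPCR cn ≠ 2 but
caller cn = 2), and any-caller accuracy.

## Synthetic-data generator

The generator emulates the statistical structure of a multi-breed equine
SNP50 CNV survey; all outputs are pure functions of `(SimConfig, seed)`
via `numpy.random.SeedSequence` sub-streams.

- **Genome**: default 5 chromosomes × 10 Mb with 2,000 uniformly scattered
  markers — a scaled-down genome that keeps every test in seconds.
  `full_scale()` gives 31 chromosomes, 48,860 markers and 717 animals for
  slow runs. Marker density (1/25 kb) matches the SNP50 chip's order of
  magnitude.
- **CNV sizes**: log-normal parameterised by (median 169,367 bp, mean
  487,562 bp) — `μ = ln median`, `σ = √(2 ln(mean/median))` — because
  median and mean are the natural printed summaries of a CNV size
  distribution. Draws are truncated at 25 % of a chromosome and loci are
  placed disjointly, each spanning ≥ 3 markers so detection is possible
  after the probe filter.
- **Sharing structure**: carrier frequency (uniform 0.02–0.30) is
  comonotone with locus size, so larger CNVs are carried by more animals
  and the shared-vs-private size contrast emerges naturally.
- **Breeds and trait**: Arabian (n = 50, 148 cm), Hanoverian (100, 168 cm),
  Lusitano (50, 160 cm); height = breed mean + β·(2 − cn at the causal
  locus) + N(0, 3 cm). The causal locus is a deletion with β = +4 cm per
  deleted copy carried by ~15 % of animals — deletion increases height.
  The within-breed sd of 3 cm is a field-plausible choice; published
  per-breed height tables give means only.
- **Callers**: sensitivities 0.20 / 0.70 / 0.80 and false-positive rates
  0.05 / 0.20 / 0.30 per sample for CNVPartition / PennCNV / QuantiSNP,
  reproducing the observed yield ordering (CNVPartition finds a small
  fraction of events; the HMM callers are comparable to each other).
  Detected breakpoints get N(0, 5 kb) jitter snapped back to ≥ 3 markers;
  copy numbers are preserved on true detections. False positives never
  overlap true loci, keeping sensitivity and FPR identifiable. Score
  distributions (QuantiSNP LBF ~ N(25, 10), CNVPartition confidence ~
  N(60, 20)) leave realistic tails below the QC cut-offs.
- **qPCR wells**: `Ct_target = 28 − log2(cn/2) + noise`, reference fixed at
  20, two replicates, homozygous deletions censored at Ct 38.

What the generator does **not** emulate: raw LRR/BAF signal, linkage
disequilibrium between CNVs, caller-specific breakpoint biases beyond
symmetric jitter, genotyping batch effects, or relatedness within breeds.
Passing tests therefore demonstrate that the *analysis machinery* is
correct and well calibrated under the stated error model, not that any
specific biological claim about real cohorts is reproduced.

## Problem sizes and tolerances

Test and acceptance runs use the scaled genome (200–400 animals, 30 loci,
1,000 permutations); parameter recovery and family-wise error are measured
over 50–100 replicate seeds. Monte-Carlo assertions use the binomial error
bound `2√(p(1−p)/n)`. Floating-point cross-checks against statsmodels are
at relative tolerance 1e-8; permutation p-values are exact given
`(seed, n_perm)`.

## Known limitations

- The consensus envelope is the union span of supporting calls, so a noisy
  flanking call can widen a region; probe-level boundary re-genotyping is
  out of scope.
- The enrichment permutation null treats regions as independently placed,
  ignoring clustering of real CNVs around segmental duplications.
- The association model treats dosage linearly; genuinely non-additive
  copy-number effects would be attenuated.
- Breed labels are taken at face value; admixed animals are not modelled.
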