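# Methods

This note records the statistical model, the synthetic-data generator, the
numerical conventions, and the design decisions behind `csskit`, in the
order the pipeline runs.

## Cohort construction

Phenotype input is a country-replicated table of per-breed average male
and female wither heights (cm). The country value is the mean of the two
sex averages; the breed value is that value for single-country breeds and
the median across countries otherwise. Breeds are classified against the
overall quartiles of all breed values: **large** requires the breed value
strictly above the overall Q3 and — for multi-country breeds — the
breed's own Q1 strictly above the overall median; **small** is the mirror
image; everything else (including ties with a quartile) is **medium**.
Both per-breed and overall quantiles use linear interpolation between
order statistics (numpy's default, "type 7"); the convention is recorded
in output metadata because the classification of breeds near a quartile
depends on it. Breeds genotyped but absent from the phenotype table are
treated as medium and logged rather than failing the run. The rule is
rank-based, so any strictly increasing transform of all heights leaves
the classification unchanged.

## Genotype handling

Input is phased VCF (or a haplotype-matrix TSV) plus a SNP map and an
ancestral-allele table. Alleles are recoded 0 = ancestral / 1 = derived;
sites that cannot be polarized (ancestral allele not among the observed
two), are absent from the map, or contain missing genotypes are dropped
and counted in the QC report. Unphased heterozygotes are a hard error —
the statistics require haplotypes, and silently treating unphased data as
phased would corrupt EHH. No imputation is performed. Coordinates are
1-based inclusive internally; BED exports are 0-based half-open.

Duplicate samples are detected from the pairwise identity-by-state matrix
IBS(i,j) = mean over SNPs of (2 − |dosage_i − dosage_j|)/2, removing the
later sample of each pair at or above the threshold (default 0.95,
configurable). Note that members of small, inbred populations can reach
IBS ≈ 0.95 without being duplicates; for such data a stricter threshold
(0.99) is the right setting, as the README example shows. MAF filtering
(default ≥ 0.01) is computed over the analysis scope — the sample set
actually scanned — and monomorphic sites are always removed; the filter
is idempotent.

## Constituent statistics

* **F_ST**: Weir–Cockerham θ in its haploid-observation form, treating
  each phased haplotype as one sampled allele. With two cohorts of n₁, n₂
  haplotypes and derived frequencies p₁, p₂: MSB = Σ nᵢ(pᵢ − p̄)²,
  MSW = Σ nᵢ pᵢ(1 − pᵢ)/(N − 2), n_c = N − (n₁² + n₂²)/N, and
  θ = (MSB − MSW)/(MSB + (n_c − 1) MSW). Sites monomorphic across both
  cohorts are set to 0. The Hudson estimator is available behind a
  config switch; because the composite uses ranks, the choice moves
  individual values but barely moves results. θ is exactly symmetric
  under cohort swap, so both scan orientations share it.
* **ΔDAF**: derived-frequency difference candidate − reference; exactly
  antisymmetric under swap.
* **XP-EHH**: at every core SNP, the extended haplotype homozygosity
  EHH(x) = Σ_k C(c_k,2)/C(n,2) is extended outward over all haplotypes of
  a cohort *combined as a single group* (EHH = 1 at the core). iHH is the
  trapezoidal integral of EHH over physical distance (bp), both sides
  summed, and xpehh_raw = ln(iHH_candidate/iHH_reference), standardized
  genome-wide. Starting instead from the core-allele partition would tie
  iHH to core-site homozygosity and hence (under ancestral-major
  polarization) anti-correlate XP-EHH with ΔDAF under the null
  (measured r ≈ −0.28); with the single-group convention all pairwise
  null rank correlations are |r| < 0.01.

EHH curves are truncated when EHH < 0.05, when an inter-SNP gap exceeds
200 kb, at chromosome ends, and at a maximum extension of 1 Mb per side.
The extension cap is standard for cross-population EHH scanners and also
prevents chromosome-scale haplotype sharing — which small drifting
populations generate in abundance — from dominating the integral. SNPs
where either cohort's iHH is 0 are excluded from ranking and propagate as
excluded through smoothing and thresholds. Physical distance is the
integration variable throughout; no genetic map is required. The
allele-specific EHH curve (carriers of one core allele, EHH(0) = 1) is
exposed separately for inspection.

The per-chromosome iHH walk is JIT-compiled with numba; a pure-numpy
reference implementation remains in `stats.py` and the test suite asserts
their equality.

## The composite score

Constituents are ranked ascending over the analyzed SNPs (larger =
stronger evidence for selection in the candidate cohort), ties receiving
mean ranks; fractional ranks r′ = rank/(n+1) map to z = Φ⁻¹(r′); the mean
z̄ over the m = 3 constituents is referred to N(0, 1/m) one-sided:
p = SF(z̄√m), CSS = −log10 p. The one-sided upper tail is used because
the directional constituents are oriented candidate-vs-reference and the
two orientations are computed as separate tracks (sharing F_ST, negating
ΔDAF and raw XP-EHH; the "negative" track of a mirrored Manhattan plot is
purely a plotting convention). Smoothing is the unweighted mean of CSS
over SNPs within ±500 kb on the same chromosome, boundary inclusive.
Threshold flags use the empirical (1 − q) quantile (linear interpolation)
of smoothed CSS genome-wide with q = 0.001 and 0.01, flagging values ≥
the cutoff; with this rule the top-0.1% count can differ by ±1 from
n/1000, and top-0.1% ⊆ top-1% always holds.

Because only ranks enter, multiplying a constituent by a positive
constant or applying exp() leaves CSS bitwise unchanged; the test suite
asserts this exactly, and it is why no allele-frequency binning is needed
in the XP-EHH standardization.

**Null behaviour.** Under permuted cohort labels each z-vector is exactly
standard normal scores and var(z̄)·m measures their dependence; on ~12k
neutral simulated SNPs it is 0.99. The p-values are *not* exactly
uniform, however: F_ST carries no direction, so its rank rises with the
magnitude of the directional statistics whichever cohort they favour.
Extreme candidate-side SNPs get 3-of-3 agreement while extreme
reference-side SNPs get 2-of-3, skewing the null z̄ slightly right
(KS distance to uniform ≈ 0.05–0.06, stable across seeds and cohort
constructions). This is a property of the rank copula of the method
itself, not of sample size; it is one reason region significance is
referred to empirical genome-wide quantiles and a permutation null rather
than to the nominal N(0, 1/m) p-value.

## Regions, genes, and nulls

A cluster is a maximal run of map-consecutive top-1% SNPs ("adjoining" is
read strictly; an optional gap-tolerant mode allows ≤ g interleaved
sub-threshold SNPs, default g = 0, and such SNPs never count toward the
cluster). A cluster qualifies as a significant region when it contains at
least one top-0.1% SNP and at least five further top-1% SNPs (total run
length ≥ 6; flanks may be one-sided — the total-count reading of "flanked
by five or more"). Region boundaries are the first and last top-1% SNP
positions; regions on a chromosome with gaps ≤ 1 Mb (inclusive) merge
transitively. Region length is (end − start)/10⁶ Mb, reported to two
decimals.

Candidate gene regions merge map-consecutive genes with inter-gene gaps
≤ 1 Mb (inclusive). Co-location means interval intersection with the gene
region padded ±1 Mb, all intervals closed (touching counts). The chance
expectation is the fraction of the autosomal genome covered by the union
of padded gene regions, clipped at chromosome ends — union, never a sum,
so overlapping padded regions are not double-counted. The permutation
null re-runs the entire scan on pseudo-cohorts drawn by random sample
assignment (breed labels ignored, samples unweighted) at the real
cohorts' sizes, and scores their regions against the same gene regions;
on neutral data its pooled co-location matches the chance expectation
within binomial sampling error.

## Synthetic data

The generator produces what the scan consumes: a phased, polarized
multibreed panel and an FAO-style phenotype table, with known truth.

* **Founders.** Per genome, SNP positions are uniform per chromosome
  (default 29 × 86 Mb, 1250 SNPs each ≈ 36k SNPs at ~69 kb spacing,
  emulating a 50K chip). Founder haplotypes (200) are mosaics over 24
  prototype haplotypes with distance-dependent switching (expected block
  ~2 Mb), giving LD on the megabase scale. Per-SNP derived frequencies
  are drawn from Beta(1.5, 1.5) clipped to [0.05, 0.95] — the flat-ish
  intermediate spectrum of an ascertained chip, not the U-shaped spectrum
  of sequencing. The ancestral allele is defined as the founder-pool
  major allele.
* **Trait loci.** Each locus gets derived-allele status on ~45% of
  prototypes, and the carrier prototypes share the origin prototype's
  local haplotype over ±750 kb — the variant arose once, so flanking SNPs
  hitchhike when it sweeps. Effects are additive; the default six 5 cm
  loci alternate sign, because derived alleles can shorten as well as
  lengthen — with the consequence (observed in real analyses too) that
  the large and small cohort orientations each detect their own loci.
* **Breeds.** Each breed is an independent Wright–Fisher population
  (default Ne = 50 diploids) seeded from the founder pool and evolved for
  30 discrete generations with recombination under a Haldane map at
  1 cM/Mb (gamete formation by parity of per-interval crossover
  indicators). A quarter of breeds are "tall" (truncation selection each
  generation keeping the top 20% by additive genetic value), a quarter
  "short" (bottom 20%), the rest neutral. Selfing is possible under
  random mating of the selected parents, as in a standard WF model.
* **Phenotypes.** Breed genetic mean = 130 cm baseline + a N(0, 2 cm)
  breed background + the realized mean genotypic value; the table holds
  one row per (breed, country) with male/female = mean ± 5 cm + N(0,
  noise sd, default 1.5 cm). With noise 0 and one country the table
  reproduces the genetic means exactly.

All randomness derives from one seed; a fixed seed gives byte-identical
output files.

**What the generator does not emulate:** admixture and migration between
breeds, ascertainment bias differing between cohorts, genotyping error,
variable recombination rate, overlapping generations, and a realistic
(coalescent) founder genealogy. Passing tests therefore demonstrate that
the pipeline recovers strong, recent divergent selection under clean
drift — not that it would have equal power on real bovine data, where
admixture and chip ascertainment add structure the null here lacks.

## Validation conditions and problem sizes

Two named configurations freeze the study conditions used by the test
suite and the acceptance script, scaled so a full run fits on one CPU in
minutes:

* `calibration_config`: 4 × 100 Mb chromosomes with 2500 SNPs each
  (~10k SNPs, 40 kb spacing), 32 breeds × 6 samples, Ne 50, 30
  generations keeping 20%, loci (+5 cm, −5 cm). Across 20 seeds, 34/40
  loci (85%) fall within 1 Mb of a called region in the correct
  orientation's track. The scale matters: the genome-wide top-0.1% flag
  budget is n/1000 ≈ 10 SNPs, and since a sweep plateau spans ~25 SNPs,
  same-track peaks compete winner-take-all — the mixed-sign design
  reflects reality *and* gives each orientation its own flag budget. The
  residual misses are orientation mixing: under two-sided divergent
  selection the ancestral allele of a "+" locus sweeps upward in short
  breeds, so its region occasionally surfaces in the other track.
* `neutral_config`: the same with selection off and five chromosomes
  (~12k SNPs after QC), used for the null-uniformity measurement and,
  with four chromosomes, the permutation-vs-chance check.

## Degenerate inputs and tie-breaks

All-identical constituent vectors rank to r′ = 0.5 everywhere with a
warning; all-equal smoothed CSS flags every SNP with a warning; a
single-SNP chromosome smooths to itself; window 0 is the identity;
fewer than 4 breeds, an empty QC scope, cohorts with zero genotyped
samples, overlapping candidate/reference cohorts, an EHH core with fewer
than two carriers, and start > end gene intervals are errors. IBS
dedupe keeps the earlier sample of a duplicate pair deterministically;
per-breed subsampling is uniform under a caller-supplied seed.

## Known limitations

* The null distribution of CSS p-values is mildly non-uniform by
  construction (see *Null behaviour*); empirical thresholds and the
  permutation null are the supported significance machinery.
* XP-EHH on cohorts below ~20 haplotypes is fragile: with few haplotypes
  the EHH cutoff truncates immediately at many cores, excluding them
  from ranking.
* The region caller's sensitivity is bounded by the top-0.1% flag budget
  (n/1000 SNPs genome-wide); panels of ≤ a few thousand SNPs cannot
  support more than one or two regions per orientation regardless of how
  many loci are truly selected.
* The permutation null re-runs the full scan per set; its cost is
  n_sets × the scan cost.
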