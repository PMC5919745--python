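# Methods

## Scope and model

`sweepscan` detects candidate selective sweeps by contrasting two
closely related populations of a diploid species, one of which (the
"case") is assumed to have experienced recent directional selection at
one or more loci. The scan sees only genotype calls: no haplotype
phase, no read depths, no genetic map. Two complementary window
statistics carry the signal.

**Pooled heterozygosity.** For each SNP, among the case population's
called haplotypes, let nMaj and nMin be the counts of the more and less
frequent allele (a tie gives nMaj = nMin). Over the SNPs assigned to a
window,

    Hp = 2 ΣnMaj ΣnMin / (ΣnMaj + ΣnMin)²,

which is the heterozygosity of a single pooled "pseudo-SNP" whose
allele counts are the window sums. Hp ∈ [0, 0.5]; Hp = 0 exactly when
no minor alleles survive in the window, the fixation profile a sweep
leaves behind. Allele counts come from genotype calls, not read depths,
because the intended input is individually sequenced samples.

**Fixation index.** Per site, with p₁/q₁ and p₂/q₂ the two allele
frequencies in each population and p_r/q_r the pooled frequencies,

    Fst = 1 − (p₁q₁ + p₂q₂) / (2 p_r q_r),

the classic one-minus-ratio of within- to total-population expected
heterozygosity. Pooled frequencies are count-weighted over callable
chromosomes, which handles missing genotypes and reduces to the simple
average for equal, fully called samples. Sites monomorphic in the
pooled sample carry no information and are skipped (counted in the run
summary). Small negative per-site values are legitimate sampling noise
and are not clamped. The window value is the unweighted mean of
per-site Fst; a variant weighted by each site's callable chromosome
count is available (`fst_aggregator="weighted"`) for callers worried
about uneven missingness, and a ratio-of-averages estimator is
deliberately out of scope since the per-site formula is the contract.

**Z-standardisation and calling.** Each statistic is standardised
genome-wide over *qualifying* windows — those with at least
`min_snps_per_window` SNPs and a defined value — using the population
standard deviation (denominator n; over thousands of windows the
distinction from the sample SD is negligible, but the population form
matches treating the window set as the complete reference
distribution). A scan whose statistic has zero spread raises a
degenerate-scan error rather than emitting meaningless Z-scores.
Outlier windows are selected by strict inequalities (ZFst strictly
above, ZHp strictly below threshold); windows without a Z-score can
never qualify. The two outlier footprints are each merged into a union
of disjoint intervals and genomically intersected; intersecting pieces
that overlap or are book-ended (adjacent by 1 bp — windows on a step
grid tile contiguously) merge into candidate regions. A same-window
AND rule (`overlap_rule="same_window"`) is available; with a shared
window grid the two rules differ only at region edges. Genes are
assigned to a region on ≥ 1 bp overlap, listed in gene-start order.

## SNP filters

* **Genotype quality.** GQ is a per-call FORMAT field, so the GQ < 20
  rule is applied per call: failing calls are set missing. A site then
  survives only if each population keeps at least `min_called_per_pop`
  (default 4) fully called genotypes — without such a rule a site could
  enter the scan with an essentially unknown frequency in one
  population. Calls lacking a GQ value pass by default
  (`missing_gq_passes`), a permissive stance that only matters for
  real-world VCFs without GQ.
* **Proximity.** SNPs with a same-chromosome neighbour strictly closer
  than 5 bp are removed — both members of each close pair, which is
  symmetric, order-independent and idempotent. A `keep_first` mode
  retains the leftmost member of each cluster instead. Comparisons
  never cross chromosomes.

Whether published pipelines applied these filters before or after
their window statistics is typically unstated; here they always run
first, and the run summary records counts at every stage so the chain
(parsed ≥ after-GQ ≥ after-proximity) is auditable.

## Window geometry

Windows start at 1, 1+step, 1+2·step, … and only windows wholly inside
the chromosome are kept. Defaults are 100-kb windows and 10-kb steps.
The step convention in the source literature is ambiguous (10-kb steps
in one place, 50%-overlap — i.e. 50-kb steps — in another); the
default follows the former and the step is configurable rather than
adjudicated. `min_snps_per_window` defaults to 20, the density below
which 100-kb window statistics were observed to destabilise in the
motivating genome-scale data.

## Synthetic data generator

The simulator produces the statistical structure the scan assumes and
nothing more:

* SNP positions follow a Poisson process (default 1 SNP per 500 bp on
  2 × 2 Mb chromosomes, ≈ 200 SNPs per window) plus a planted 0.5% of
  SNPs placed 1–4 bp from a neighbour so the proximity filter is
  always exercised.
* Background allele frequencies follow the Balding–Nichols model: an
  ancestral frequency π ~ Beta(0.8, 0.8) per SNP (mildly U-shaped, as
  empirical site-frequency spectra are), then per-population
  frequencies Beta(π(1−F)/F, (1−π)(1−F)/F) with F = 0.05 — mild
  background divergence typical of related breeds.
* Inside each planted sweep interval (default one 150-kb interval per
  genome), population 1's minor-allele frequency is capped at 0.02
  (near fixation) and population 2 draws uniformly from 0.3–0.7, i.e.
  low Hp in population 1 and high Fst between the populations.
* Genotypes are Binomial(2, p) per individual (8 + 8 diploids by
  default, mirroring a small resequencing design); GQ is 60–99 except
  for a planted 1% of calls in 0–19, exercising the GQ filter.

It does **not** emulate linkage disequilibrium, recombination,
demographic history, genotyping error beyond the GQ labels, or
read-level noise. Passing tests therefore demonstrate that the
pipeline recovers frequency-level sweep signatures under the model's
assumptions — not that it is robust to LD-induced autocorrelation or
complex demography in real data, where threshold calibration remains
the analyst's responsibility.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere in memory; BED's
  0-based half-open convention exists only at file boundaries.
* Only biallelic SNPs enter the scan; multiallelic sites are skipped,
  not split, because the major/minor dichotomy in Hp has no natural
  multiallelic extension.
* An empty window (ΣnMaj + ΣnMin = 0) or a window with no usable Fst
  site gets NaN for the affected statistic, never qualifies, and is
  excluded from the Z-transform.
* Hp is scanned in the first population of the population map by
  default; `hp_population` selects the other.
* All simulation randomness flows from a single `numpy` Generator
  seeded by `SimConfig.seed`; dataset emission is byte-reproducible.
* Default test and benchmark problem sizes (2 × 2 Mb, ≤ 200-SNP toy
  genomes for brute-force oracles, 20 seeds for recovery rates) are
  chosen as the smallest scales at which window statistics stabilise
  and rates are meaningful.

## Verification strategy

The test suite checks every formula against hand-computed or
exact-rational values, checks the streaming window aggregation and the
region caller against independent brute-force re-computations (per
window and per base pair), and property-tests the invariants: Hp
bounds, Fst symmetry under allele relabelling and population exchange,
monotonicity of Fst in frequency divergence, zero-mean/unit-SD of
Z-scores, idempotence and partition-commutativity of the filters, and
threshold monotonicity of total called bp. End-to-end benchmarks
recover a planted sweep at ≥ 50% reciprocal overlap across seeded
replicates and call nothing on sweep-free simulations at stringent
thresholds. A published sheep tail-morphology candidate table serves as
a worked annotation example (with one obvious coordinate typo in its
source corrected); its genome-scale Z-values themselves are not
reproducible from desk-scale data and are not targets.

## Known limitations

* Window Fst aggregation and the Z-transform treat windows as
  exchangeable; sweeps broad enough to shift the genome-wide mean would
  bias thresholds.
* No FDR or significance calibration is attached to the fixed Z
  cut-offs; region calls are outlier descriptions, not tests.
* Chromosome lengths default to VCF contig headers (or the last SNP
  seen); windows beyond the last contig-declared base are never built.
* The X chromosome is treated as autosomal (all samples diploid).
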