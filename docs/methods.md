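# Methods

This note records the models, defaults, numerical choices and known
limitations of `panelcall`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## SNV/InDel calling

### Model

Each pileup column carries, per read: the observed allele (reference base,
substitution, insertion `+SEQ`, or deletion `-N`), the Phred base quality
(for InDels, the minimum of the two flanking base qualities — a
conservative choice, since no single base carries an InDel's quality), the
strand, and the distance to the nearer read end.

The caller tests the homozygous-reference null — all non-reference bases
are sequencing error — with a binomial upper tail. For quality floor
`Q_t`, bases below the floor are discarded, the error rate is taken from
the *lowest retained* quality (`e = 10^(-q_min/10)`; the floor exists
precisely so that one outlier base cannot set `e` for the whole column),
the most frequent variant allele among retained bases supplies `k`, and
`P = P(Binomial(n, e) >= k)` over the `n` retained bases. The score is
`-10·log10(P)`. The test repeats for every `Q_t` in 20..30; a variant is
reported if the score exceeds the threshold at any floor, with the lowest
such floor recorded. If different alleles win at different floors, the
highest-scoring allele is reported. Ties between equally frequent alleles
at one floor break deterministically: substitutions before insertions
before deletions, then lexicographically.

`%SR` (supporting-read percentage) and the alt count are always quoted
against the **full** column depth, not the quality-filtered depth, because
the downstream filters and detection-limit statements are phrased against
raw coverage.

### Numerics

The binomial tail is evaluated as the regularized incomplete beta function
`I_e(k, n-k+1)` (exact and stable to n ~ 1e5). When the tail underflows
double precision the log10-probability is recovered by log-space summation
of the leading 400 pmf terms — the tail decays geometrically, so the
truncation error is far below one ulp. The test suite pins the
implementation against an explicit-summation oracle for all n ≤ 200 at
1e-10 relative tolerance.

### Defaults and filters

| knob | default | rationale |
|---|---|---|
| quality floors | 20..30 | sweep range balancing outlier-robustness against discarding real signal |
| score threshold | 50 (strict >) | Phred scale: null probability below 1e-5 |
| minimum coverage | 150× | depth at which ~7% VAF is reliably detectable; below it columns are flagged, not called |
| %SR low-confidence | < 2 | below panel error floor for FFPE material |
| InDel homopolymer filter | %SR < 10 in a run ≥ 6 | polymerase slippage produces exactly this signature |
| tail-distance bias | rank-sum p < 1e-5 | artifacts (FFPE damage, alignment clips) cluster at read ends |

Filtered calls are retained with a FILTER status (VCF semantics), never
dropped: a reviewer can always see what was suppressed and why. Strand
bias (Fisher exact on the ref/alt × strand table) and base-quality bias
(rank-sum) are reported but do not filter.

The rank-sum test enumerates the permutation null exhaustively when the
number of group assignments is at most 2e5 and otherwise uses the
tie-corrected, continuity-corrected normal approximation. An exact test
for the typical low-VAF geometry (e.g. 16 alt vs 384 ref tail distances)
would need an astronomically large enumeration, and a Monte-Carlo
permutation would make call results depend on an extra random stream; the
normal approximation is deterministic and accurate at these group sizes.

## Copy-number calling

Normalized coverage is reads per base per million on-target reads — the
scale constant is arbitrary (all downstream quantities are ratios) and
chosen only for readability. GC correction is mean-based and additive:
regions are binned by GC at width 0.02, bins with fewer than 3 regions
merge into the nearest populated bin, and each region is shifted by the
negative of its bin's deviation from the global mean.

The normal profile is built by iterative outlier elimination. Each round
scores every surviving sample per region with a **leave-one-out** Z —
against the mean/SD of the other surviving samples. This is deliberate:
with a pooled SD that includes the candidate, the maximum attainable |Z|
in a cohort of n samples is (n−1)/√n (1.79 for n = 5), so a Z > 3 cut-off
could never remove a gross outlier from a small cohort; leave-one-out
removes the self-masking. A sample with |Z| > 3 in more than 10% of
regions is dropped; iteration stops when no sample is dropped or two
remain. The final per-region SD is floored at 5% of the mean so
near-constant regions cannot produce unbounded Z.

Copy number is anchored at diploid = 2 (`CN_r = 2 × sample_r / mean_r`),
which is what makes the 2.7 amplification and 1.2 deletion thresholds
directly interpretable as fold changes of a diploid genome.
Amplification requires CN > 2.7 in a *strict* majority of a gene's
regions; deletion requires a single region below 1.2. The high-confidence
tier requires the size-weighted gene CN past the threshold and |Z| > 3 in
at least half the supporting regions — a deterministic stand-in for manual
inspection of the coverage profile. An optional cohort file of previously
observed weighted CNs can tighten this with an interquartile-range check.

Known limitation: mean-based additive GC correction is not robust to the
CNV events themselves. On small panels where one amplified gene is a large
fraction of the target, its regions contaminate their GC bins and the
library-size normalizer, shrinking all CNs toward 2 and occasionally
pushing low-efficiency regions under the deletion threshold. At realistic
panel scale (~hundreds of regions, an event gene a few percent of the
target) the effect is second-order; the simulators and tests use
panel-scale manifests for exactly this reason.

## Translocation calling

Evidence is a read with exactly two mapped segments (from SAM
supplementary-alignment tags or a split-segment TSV), each spanning ≥ 25
aligned bases, on different chromosomes or > 100 kb apart. Within a gene
pair, the modal breakpoint pair defines the cluster; reads within ±5 bp on
both breakpoints are consistent, and coherence requires a strict majority
consistent — a quantitative replacement for visual browser inspection,
with a per-cluster evidence dump (read id + breakpoints) emitted for
audit. Reporting requires ≥ 8 consistent reads; clusters with 6–7 reads
surface as `below_threshold` rather than being auto-reported, and
≥ 8-read clusters between genes not on the known-partner list are flagged
`needs_confirmation` for an orthogonal method.

## FFPE QC

Deamination-type calls are ref C→T or ref G→A substitutions (the same
chemistry seen from either strand; a strict C>T-only mode is available
since convention varies). The gates — deamination share > 0.45 among
substitutions at ≥ 5 %SR, or > 500 such variants — are strict
inequalities, so a sample exactly at a cut-off passes. Coverage metrics
report mean depth and the percent of target bases at ≥ 100× and ≥ 200×;
the duplicate fraction is echoed from upstream (duplicates are marked by
the aligner pipeline and honored, never re-computed here).

## Limit-of-detection framework

Downsampling composes each derivative column **exactly**: `k =
round(vaf × depth)` variant observations (round half up, so 7% of 150 →
11) and `depth − k` reference observations, drawn without replacement from
independent source pools. This mirrors choosing separate read subsets for
variant- and reference-carrying reads and makes "detected with probability
1" claims well-posed: at fixed Q30 qualities the call decision is a
deterministic function of the composition, and grid cells are exactly 0
or 1. Detection probability per (coverage, VAF) cell is the fraction of
seeded replicates in which the truth allele returns as a PASS call with
post-filters applied. The default is 200 replicates of one locus;
many-loci mode is available by supplying a different source factory.

Sensitivity matches on (chrom, position, allele) after left-normalization
of InDels (the pileup layer anchors InDels at their leftmost equivalent
position). Specificity is (assessed − false positives)/assessed over
variant-free positions. Concordance is squared Pearson correlation of
paired %SR vectors.

## Synthetic data: what it does and does not emulate

The generators state a fixed world:

- **Pileups**: depth negative binomial (mean 800, dispersion 0.05 —
  capture coverage is super-Poisson), base qualities a point mass at Q30
  or a 90/10 Q30/Q20 mixture, read length 150 so tail distances are
  uniform over `min(offset, 149 − offset)`, strands alternating. Errors
  flip a reference base to a uniformly random wrong base with probability
  `10^(−q/10)`. Truth variants are planted at exact count (downsampling
  convention) or by binomial draw (sequencing-replicate convention).
- **FFPE noise**: at C/G reference columns, with a configurable
  per-column rate, reference reads are converted to the deamination allele
  at a VAF drawn from Uniform(0.05, 0.15) — the low-frequency band
  fixation artifacts occupy.
- **CNV counts**: expected count ∝ region size × GC-efficiency curve ×
  reproducible per-region capture efficiency × purity mixture
  `(2(1−f) + f·CN)/2`. The capture efficiency is lognormal with CV 0.2,
  keyed deterministically on the region id so every sample shares it —
  this reproducible component, which the normal profile absorbs, carries
  most of the wide marginal regional spread of real capture data; the
  per-sample residual is negative binomial with dispersion 0.005 (~8% CV).
  Modeling the full spread as independent per-sample noise would make
  profile-based calling impossible for any caller, not just this one.
- **Split reads**: chimeric read count Binomial(spanning reads, capture
  probability × tumor fraction), so support falls in proportion to
  dilution; a minor fraction of reads carry ±2 bp breakpoint jitter to
  exercise the consistency rule.

Not emulated: alignment itself (mapping ambiguity, soft-clip artifacts),
PCR duplicates, strand-correlated FFPE damage, subclonal structure,
germline contamination of the variant spectrum, and inter-run batch
effects. A green simulation test therefore establishes the correctness of
the calling logic and its thresholds under the stated noise model — not
the behaviour of any wet-lab assay.

## Reproducibility

Every generator and every sampling operation takes an explicit seed, and
every pipeline stage writes a run manifest (config + seed + version) next
to its outputs; rerunning a stage with the same config and seed reproduces
its primary outputs byte for byte. All calling is deterministic given the
column (observation order is irrelevant).
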