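# Methods

`gutbench` implements the computational evaluation layer of a gut-metagenome
profiling workflow: scoring observed taxonomic profiles against known mock
communities, calibrating host-read filtering from alignment match-length
distributions, assessing spike-in isolation bias from genome coverage, and the
statistical battery used to attribute composition differences to protocol
factors. This note records the models, the parameters that matter, and the
choices made where the design was genuinely open.

## Abundance scale and taxon identity

All profiles are carried as **percent of classified reads at a fixed rank**,
summing to 100 per sample. This is the scale on which the two profiler
families become comparable: Bracken reports abundance relative to classified
reads, while MetaPhlAn reports it relative to the whole input, so
MetaPhlAn-style profiles are rescaled by the classified fraction
(`renormalize_to_classified`). Kraken-report abundances are recomputed from
clade read counts rather than taken from the printed percent column, which is
rounded to two decimals. Expected-community tables are accepted when their
stated abundances sum to 100 within 0.1 (manufacturer sheets round per-species
values) and are then renormalised exactly; larger drift is an error.

Taxa are matched across tools by NCBI taxid when both sides carry one, else by
a normalised name (lowercased, rank prefixes such as `s__` stripped,
underscores mapped to spaces, whitespace collapsed; the normalisation is
idempotent). Sub-species/strain rows are aggregated into their parent species
before species-rank comparison; for Kraken reports this is implicit because
clade counts at species rank already include strain reads.

## Reconstruction metrics

For an observed profile against an expected community, a taxon counts as
*detected* iff its observed abundance exceeds `detection_threshold`
(default 0: any positive abundance counts, so negligible-abundance artifact
species are charged as false positives). The metrics are

- **recall** = 100·|TP| / (|TP|+|FN|),
- **traditional precision** = 100·|TP| / (|TP|+|FP|),
- **weighted precision** = summed observed abundance of TP taxa — the
  abundance-weighted analogue that is robust to swarms of negligible false
  positives (for a normalised profile with threshold 0 it equals 100 minus
  the false-positive mass),
- **abundance RMSE** = √(mean (expected−observed)²), in percentage points.

RMSE has two modes: `tp_only` (default) averages over correctly identified
taxa only, so misses are not double-charged against abundance accuracy;
`all_expected` averages over every expected taxon with observed = 0 for
misses. The modes coincide when recall is 100%.

## Beta diversity

Bray–Curtis is implemented in its standard quantitative form,
`1 − 2·Σ min(p_t,q_t) / (Σ p_t + Σ q_t)` over the union of taxa — the form the
vegan package computes on abundance tables. A binary (Sørensen-like)
simplification sometimes appears in prose descriptions; it is not implemented
because the quantitative form is what abundance-table workflows actually
compute. Hierarchical clustering uses scipy with average linkage (UPGMA) by
default (complete and single are available); samples are ordered
lexicographically before agglomeration so ties break reproducibly, and trees
serialise as newick with branch lengths derived from merge heights.

## Host-read calibration

Reads mapped against a host genome form two populations: true host reads
aligning over (nearly) their full length, and short-overlap spurious mappings
from regions shared between host and bacterial genomes. Match length is
defined as the sum of CIGAR operations that align query to reference
(M/=/X) — alignment score and edit distance are deliberately not used.
Only primary alignments count (fractions are per read, not per alignment),
and reads shorter than `min_read_length` (default 140 bases, matching the
preprocessing length filter for 150-base reads) are excluded up front.

The two populations are separated on a 1-base histogram of match lengths,
zero-padded and smoothed with a moving average (window 5, the smallest window
that removes single-bin noise in the fixtures; configurable). Among all pairs
of local maxima, the pair with the deepest valley between them is chosen,
subject to the valley being at least `min_valley_depth` (default 0.5) of the
smaller mode — this rejects twin sub-peaks inside one population, which can
otherwise tie on height or prominence. The split point is the minimum density
strictly between the chosen modes; a histogram with no qualifying pair is
reported as effectively unimodal with instructions to use an explicit fixed
split. A fixed-split mode is provided because the short-overlap boundary may
also be chosen by inspection.

The recommended minimum seed length is the 95th percentile (configurable) of
the false-positive match lengths, computed by linear interpolation between
order statistics and rounded up to an integer number of bases. Re-running the
aligner with the raised seed is out of scope; filtering records by
`match_length ≥ seed` is the decision-equivalent operation, and the host
fraction is the percentage of *all* reads (mapped or not) passing that filter.

## Spike-in coverage

Coverage tracks use 0-based half-open coordinates and store merged
constant-depth runs, built by a sweep-line over alignment intervals (verified
against a per-position counter in the tests). Breadth is the fraction of
genome positions with depth > 0; depth is summarised as the position-weighted
median over covered positions, using the lower of the two central order
statistics for even counts so the result is always an attained integer depth.

Signal classification encodes the coverage-shape dichotomy: genuine low-level
presence is *broad_low* (breadth ≥ 0.05 and median depth ≤ 5×), shared-region
mapping artifacts are *narrow_high*, and zero breadth is *absent*. The
thresholds sit between the two regimes observed in practice (genuine
presence at breadth ≳ 0.06 and 1–2×; artifacts at breadth ≲ 0.02 and
17–227×) and are configurable. Isolation bias between two spike genomes is
summarised by two ratios — covered fraction of A over B and median depth of A
over B — with undefined ratios flagged rather than raised. Multi-mapping
reads are not deduplicated (an aligner distributes them randomly at MAPQ 0,
so they are not expected to inflate breadth systematically); an optional
MAPQ ≥ 1 filter is available when reading SAM.

## Statistical battery

**Gram ratio.** Summed gram-positive abundance over summed gram-negative
abundance (abundance sums, not species counts), computed identically for the
observed profile and the reference; a zero gram-negative sum flags the ratio
undefined.

**Correlation.** Pearson r of observed vs manufacturer abundance per gram
group, over taxa present in both; groups with fewer than two shared points or
zero variance (even mixes) are omitted rather than reported as undefined
numbers.

**OLS + top-down selection.** Ordinary least squares (statsmodels) of a
response — typically median species abundance — on gram status, genome length
and GC content, with two-sided t-test p-values. Backward elimination drops
the least significant term while any term has p ≥ α (default 0.05), never
drops the intercept, and records the elimination order. The procedure can
never terminate with a retained term at p ≥ α, which is asserted in the
tests. Exact recovery of a single planted effect is capped near
(1−α)² × power, because each null covariate is falsely retained with
probability ≈ α; at α = 0.05 with two null covariates this cap is ≈ 0.9,
which the recovery simulations reproduce (≈ 86–89% over 200 seeds).

**Wilcoxon rank-sum.** Two-sided; the statistic reported is the rank sum of
the first sample. Mode `auto` uses the exact distribution for combined
n ≤ 20 without ties (scipy) and the tie-corrected normal approximation with
continuity correction otherwise; `exact` with ties falls back to a full
midrank enumeration. Per-clade pairwise tests across groups treat a missing
clade as abundance 0 and adjust all raw p-values jointly.

**FDR.** Benjamini–Hochberg step-up (statsmodels), order-preserving and
capped at 1; "the FDR method" is taken as BH, the stats-package default.

**PERMANOVA.** Distance-based, after McArdle & Anderson: squared
dissimilarities are Gower-centred into an inner-product matrix G; for an
ordered term list (e.g. `time + kit + time:kit`) sums of squares are
sequential (Type I), computed as successive differences of tr(H·G) under the
cumulative hat matrices, so each term is adjusted only for the terms before
it. Pseudo-F per term is (SS/df) / (SS_res/df_res); R² per term is
SS/SS_total, and term R² plus residual R² sums to 1 by construction.
Significance uses free whole-row label permutation with the add-one
convention p = (1 + #{F* ≥ F}) / (1 + n_permutations), so the smallest
attainable p is 1/(n+1) — e.g. 0.001 at 999 permutations. Factors with one
level, collinear terms, and formulas without residual degrees of freedom are
rejected. Type II/III sums of squares and restricted permutation strata are
out of scope. Whether a main-effects-plus-interaction table comes from one
sequential model or separate fits is ambiguous in common usage; a single
sequential model is implemented.

## Synthetic data

The generators produce every input the pipeline consumes, with ground truth
retained, and are pure functions of their spec including the seed.

- **Communities**: n species (default 12, 4 gram-positive — the whole-cell
  mock layout) with even abundance (100/n ≈ 8.33% each) or log-normal
  staggered abundance (exp N(μ, σ²) weights normalised to 100; defaults
  μ = 1, σ = 1, the conventional log-normal community parameterisation).
  Genome lengths are drawn uniformly from 1.8–6.5 Mbp and GC from 0.28–0.60,
  the ranges typical of gut bacteria.
- **Observed profiles**: surviving true species keep their reference
  abundance times a multiplicative log-normal factor with mean 1 and
  coefficient of variation `abundance_cv`; each species drops out
  independently with probability `dropout` (resampled up to 10 times if
  everything drops). False-positive species carry geometrically decaying
  abundances whose total is `fp_total_abundance` percent **of the final
  profile** — true species are scaled to the complement, which makes
  weighted precision exactly 100 − fp_total under no other noise and mirrors
  how artifact species dilute the mass on correct taxa.
- **Read populations**: true host reads at MAPQ 60 with match lengths
  140–150 of a 150-base read; short-overlap false positives mostly at
  MAPQ 0 (probability 0.9). Dict-valued match-length distributions are
  deterministic compositions (largest-remainder apportionment), tuple-valued
  ones are sampled discrete-uniform. The default false-positive distribution
  places 95% of its mass uniformly on 10–21 bases with a sparse 5% tail at
  26 — the empty gap above its 95% point is what makes percentile-based seed
  calibration clear the bulk entirely; for a distribution with appreciable
  mass at its own 95th percentile, a `match_length ≥ seed` filter
  necessarily retains at least ~5% of false positives, a quantile identity
  worth keeping in mind when transferring the calibration to real data.
  Records serialise to SAM with `<match>M<rest>S` CIGARs.
- **Coverage**: *broad_low* covers each position independently at depth 1
  with probability p (default 0.3); *narrow_high* places one run of 0.5% of
  the genome at depth 100. These bracket the two regimes the classifier must
  separate.

What the generators do **not** emulate: sequence content and read-level error
profiles, classifier-specific confusion structure (false positives are
abstract artifact species, not phylogenetic neighbours), correlated dropout,
GC-dependent coverage bias, and library-size variation. Passing tests
demonstrate that the evaluation layer recovers planted structure under these
idealised conditions; they do not certify profiler accuracy on real reads.

## Numerical conventions

Percent sums are validated to 1e-6; reference-table drift up to 0.1 is
renormalised. The canonical profile TSV writes abundances with `repr` so
round-trips are exact to 1e-9. Permutation comparisons use F* ≥ F − 1e-12 to
avoid excluding exact ties. Agglomeration, permutation and simulation seeds
are explicit everywhere; re-running a pipeline config with the same seed is
byte-identical across outputs.

## Problem sizes used in the test and acceptance runs

Property batteries run at sizes chosen to make the checks exact or tightly
concentrated while remaining quick on one CPU: 1000 random profile pairs for
the Bray–Curtis oracle, 500 null simulations at 199 permutations (n = 12
samples) for PERMANOVA type-I calibration, exhaustive Wilcoxon enumeration
for all combined n ≤ 12, 100 seeds at 1000+1000 reads for host-calibration
recovery, 200 seeds at n = 12 for model-selection recovery, and 100 seeds at
100 kb genomes for the coverage-regime dichotomy.

## Known limitations

- The valley detector assumes two separated populations; heavily overlapping
  match-length populations require the fixed-split mode.
- PERMANOVA offers free permutation only; designs needing restricted strata
  (repeated measures) are out of scope.
- The exact Wilcoxon path with ties enumerates all C(n, n_x) assignments and
  is only intended for small groups.
- Gram-ratio and correlation analyses require gram annotations in the
  reference table; unlabeled taxa are silently excluded (and logged).
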