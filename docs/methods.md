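# Methods

This note documents the models, algorithms, and numerical choices
behind ampliquery, in the order data flows through the package.

## Data model and formats

Count tables are strictly integer, samples × features in memory,
features × samples on disk (the BIOM orientation). Real-valued input is
rejected rather than rounded: rarefaction treats each sample as a
multiset of reads, which only makes sense for integers. File order of
samples and features is preserved through every reader and writer so
that runs are byte-reproducible.

Supported dialects are the tab-delimited dense matrix with a `#OTU ID`
header and BIOM classic JSON 1.0 with dense or sparse `data` (the
reader/writer is a direct implementation of that JSON layout; HDF5 BIOM
2.x is out of scope). Metadata follows the EMP mapping-file convention:
first column `#SampleID` (or `sample_name`), everything read as
strings. Empty cells and the literals `NA`/`na` become a MISSING
sentinel that is excluded from category enumeration — otherwise "NA"
would surface as a spurious testable category.

## De novo OTU construction

The workflow operates on fixed-length 5′-trimmed reads (default
100 bp). Reads shorter than the trim length are discarded; keeping them
would break the positional comparisons below. After trimming,
identical sequences are merged with their counts summed (the total
equals the number of retained reads), singletons are removed, and
near-identical sequences are preclustered.

**Distance.** All distances are Hamming mismatch fractions on the
equal-length trimmed sequences, with `N` matching only `N`. This is a
deliberate simplification relative to pipelines that align against a
reference before computing distances: fixed-length trimming makes
position-wise comparison well defined without an alignment step, at the
cost of treating indels as mismatches. Reference alignment, chimera
detection, and classifier execution are upstream concerns — the
pipeline accepts classifications as input and exposes a hook for an
externally produced chimera id blacklist.

**Preclustering** is greedy in strictly descending abundance order
(ties by lexicographic sequence): each unabsorbed record becomes a
survivor and absorbs all later unabsorbed records within `max_diffs`
(default 1) mismatches, adding their counts. Absorbed records cannot
re-absorb, so any two survivors differ at more than `max_diffs`
positions and total count is conserved. The ordering rule makes the
result independent of input order.

**Clustering** is agglomerative complete linkage (furthest neighbour):
merges happen in ascending order of the maximum pairwise inter-cluster
distance while it does not exceed the cutoff (default 0.03, the
conventional 97% similarity level), so every cluster's diameter is
bounded by the cutoff and the clusters partition the input.
Equal-distance merges are resolved by the lexicographically smallest
pair of sorted member-index sets. The implementation is written
in-package rather than delegated to a generic hierarchical-clustering
routine because mismatch counts on short sequences are heavily tied and
the tie-break must be specified exactly for results (and the
brute-force comparison in the test suite) to be deterministic.
Internally distances are integer mismatch counts compared against
`floor(cutoff·L + 1e-9)`, avoiding float-threshold edge cases at
exactly the cutoff.

**Representatives** minimise mean distance to the other members, with
ties broken by larger count and then lexicographic sequence order —
permutation-invariant by construction. **Consensus taxonomy** walks the
ranks from domain downward and keeps a taxon while its count-weighted
member share is at least the threshold (default 0.51; thresholds must
exceed 0.5 so at most one taxon can win a rank), truncating at the
first rank without a winner. With multiple reference databases a
sequence is removed by the blacklist filter (eukaryotes, chloroplasts,
mitochondria, unknowns) if *any* database places it in a blacklisted
taxon, or if no database classifies it.

## Rarefaction

Each sample is subsampled without replacement to the target depth
(default 5000 reads/sample); samples below the depth are dropped. The
draw is multivariate hypergeometric over the sample's feature counts —
exactly the distribution of drawing `depth` reads uniformly from the
sample's read multiset. Each sample uses its own random stream derived
from `(seed, crc32(sample_id))`, so results are independent of sample
order and bit-reproducible. Features left with all-zero columns are
kept and logged rather than silently removed, so feature indices remain
stable across tables. The query service rarefies once at load time with
a configured seed and serves every query from that snapshot,
trading per-query resampling variety for query-to-query consistency.

## Enrichment statistics

Presence means count > 0 on the rarefied table. `N` and `O(s)` are
computed over all samples; `T(v)` and `K_v(s)` over samples whose
(non-missing) value equals `v`. Within any fully observed field the
values tile the samples, so Σ_v T(v) = N and Σ_v K_v(s) = O(s); the
enumeration asserts the missing-value-restricted version of these
identities internally on every run.

The binomial P-value is evaluated through the regularised-incomplete-
beta CDF (scipy) in the complementary form
`cdf(T−K, T, 1−P_null)`; degenerate nulls behave correctly without
special cases (a sequence present everywhere has P = 1, as does K = 0),
and results are floored into (0, 1]. The test suite checks agreement
with direct pmf summation to 1e−12 absolute and strict monotonicity in
K.

The ranksum test is a two-group Kruskal-Wallis on midranks with the
standard tie correction 1 − Σ(t³−t)/(n³−n), with P from the χ²(1) upper
tail; if every pooled observation is tied, H = 0 and P = 1 (scipy's
implementation raises on this case, which is why the statistic is
computed in-package; scipy serves as a cross-check in the tests).
Relative frequencies are count/depth on the rarefied table — a constant
denominator, so the test is effectively rank-on-counts. Each value is
tested against its complement (two groups, 1 df) rather than jointly
across values, and only positive rank differences (enrichment inside
the category) are reported. The χ²(1) tail is asymptotic: at pooled
n = 20 it tracks an exact permutation null to Monte-Carlo precision in
the decision tail (P ≲ 0.1) but can deviate by a few hundredths in the
middle of the null distribution, which does not affect significance
calls.

Multiple testing is Benjamini-Hochberg within each (field, test) family
at default α = 0.1. The family definition matters: BH controls the FDR
*within* a family, so pooling flags across many families that are pure
null does not inherit the α guarantee. The planted-effect validation
therefore scores the enrichment lists of the effect-carrying features,
and a separate calibration check verifies that on effect-free surveys
the uncorrected binomial rejects at most ~5–6% of pairs at P ≤ 0.05
(the discreteness of the statistic makes it conservative).

Numeric-looking metadata values are treated as distinct categories —
every unique value is tested; binning a continuous covariate would be a
different analysis. No minimum group size is imposed by default.

## Synthetic surveys

The generator emulates a categorical-metadata survey: per sample,
field values are drawn independently from the configured category
probabilities; each feature is present by a Bernoulli draw (background
presence 0.3, or a planted effect's `p_in`/`p_out`); counts are then
multinomial over the present features at a depth drawn uniformly from
the depth range. Presence and abundance are generated separately so the
binomial and ranksum tests probe distinct signal channels. Present
planted features receive their target relative frequency exactly (their
multinomial weight is scaled against the sum of the present background
weights, which follow per-feature lognormal(0, 1) base weights);
background features share the remainder proportionally.

Defaults — 200 samples, 300 features, depths uniform on [2000, 8000],
two fields (four host categories at 0.25 each; three site categories at
0.5/0.3/0.2) — are the scale at which every validation experiment runs
in seconds while leaving dozens of samples per category. The
planted-recovery experiments rarefy this design at depth 2000 so that
no sample is dropped and presence/absence structure is preserved
exactly.

Per-sample random streams are keyed by `(seed, sample_id)` exactly as
in rarefaction, so surveys are reproducible and order-independent.

What the generator does *not* model: ecological covariance between
taxa, phylogenetic signal, spatial or temporal autocorrelation, and
compositional artefacts beyond the mild coupling the multinomial
normalisation itself introduces. Passing the validation experiments
therefore demonstrates that the statistics recover planted signal and
stay calibrated under exchangeable nulls — not that real surveys, with
correlated taxa and structured noise, will show the same operating
characteristics.

## Validation problem sizes

The standing experiments use: 10 000 random prevalence configurations
(T ≤ 1000) for the binomial oracle; 10 000 permutations at pooled
n = 20 for ranksum calibration; 10 000 rarefaction replicates for the
hypergeometric goodness of fit (χ², bins pooled to expected ≥ 5,
α = 0.01); 200 random instances of ≤ 12 length-20 sequences for the
clustering/brute-force comparison; and 20 surveys of 200 samples × 300
features with ten planted effects (p_in = 0.8, p_out = 0.1) for
recovery, which attains sensitivity 1.0 at empirical FDR ≈ 0.04. These
sizes give stable statistics at seconds-to-a-minute runtimes.

## Known limitations

* Hamming-on-trimmed-prefix distances ignore indels and anything past
  the trim length; sequences differing only beyond 100 bp are merged.
* The query service matches by exact 5′ prefix only — no mismatch
  tolerance, no k-mer search.
* BIOM support is classic JSON 1.0 only (no HDF5), metadata is
  categorical only, and the REST layer is a single-process stdlib HTTP
  server intended for local or lightly loaded use.
* The complete-linkage implementation recomputes linkage pairs
  per merge (quadratic in active clusters per step); it is built for
  correctness and determinism at validation scales, not for clustering
  hundreds of thousands of uniques.
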