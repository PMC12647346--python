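# Methods

## The statistic

For a proteins × samples abundance matrix X with missing cells, the
pipeline computes the all-vs-all Spearman correlation of the zero-imputed
rows: missing cells are set to 0, each row is rank-transformed (average
ranks for ties), and ρ(i, j) is the Pearson correlation of the rank
vectors. Spearman is used because protein intensities are heavy-tailed and
only monotonically related across platforms; rank correlation is invariant
to any strictly increasing per-protein transform of fully observed vectors,
so the choice of raw vs log intensities is immaterial except where
zero-imputation creates ties (see Limitations).

Zero imputation encodes the assumption that a missing cell means the
protein was *absent or below the detection limit* in that sample, not
missing at random. For proteins with substantial biological on/off
variation across samples (common for chromatin-associated proteins in
pan-cancer cohorts), shared detection patterns are themselves signal, and
imputing zeros lets the rank correlation use them. Undefined correlations —
a constant rank vector, which under zero imputation means a protein
detected in no sample (or with identical values everywhere) — are stored as
0 in the matrix, mirroring the imputation convention; a boolean
`defined_mask` preserves the distinction for diagnostics but downstream
statistics consume the stored zeros.

Queries rank all N proteins by ρ(bait, ·) in descending order. No p-values
or cutoffs are attached anywhere in the correlation path: the method's
premise is that even modest correlations are informative when *ranked*
against thousands of alternatives. Ranks are dense 1..N over the whole
pool; `include_self` defaults to true so a bait heads its own table at
rank 1, matching how published top-k tables are laid out. Ties in ρ break
by partner identifier (ascending), which makes rankings canonical under
any permutation of the input rows.

## Validation statistics

Two dataset-level coherence checks, each a median-shift statistic:

* **Term coherence.** For each annotation term (a flat protein set, no
  ontology propagation), the median of all unordered within-term pair
  correlations, excluding values exactly equal to 1 — near-certain
  duplicate entries of one protein rather than biology. Exact equality is
  tested after rounding to 12 decimals so floating-point representations
  of perfect monotone pairs are caught. The summary statistic is the
  median of term medians minus the background median.
* **Pair enrichment.** The median correlation over a curated pair list
  (e.g. synthetic-lethal pairs restricted to low-throughput/CRISPR
  evidence) minus the same background.

The background median is taken over all off-diagonal unordered pairs with
no "=1" exclusion: the exclusion exists to remove duplicate-protein
artifacts *within* small term sets, where a single duplicate dominates a
median of few values; in the ~N²/2 background it is numerically
irrelevant, and leaving the background untouched keeps it a property of
the dataset alone. Both conventions are configurable. Term-size floor
`min_pairs` defaults to 1 (no floor); every excluded term or pair is
reported with its reason so filtering stays auditable.

## Panel summaries

For an ordered panel of proteins: the ρ submatrix in panel order (absent
members reported, never silently dropped); per-protein quartiles of its
correlations to all other proteins (self excluded by default, flag
provided); per-protein quartiles of its zero-imputed abundances plus a
detected-sample count ("detected" = unmasked and strictly above a
threshold, default 0); and mean undetected-sample count over the panel
minus user exclusions. Quartiles use linear interpolation between order
statistics (numpy's default, the "type 7" rule) — fixed so printed values
are reproducible. Under zero imputation, a protein detected in fewer than
half the samples necessarily has median = Q1 = 0, and below a quarter of
the samples Q3 = 0 as well; this is the expected signature of sparsely
detected proteins, not an error.

## Depletion contrast

Two conditions with ≥2 replicates each (typically 4+4). Intensities are
transformed as log2(x + pseudo) with pseudo-count 1 intensity unit
(configurable; it only matters near zero). Per protein: log2FC is the
difference of condition means; the p-value is a two-sided Welch
(unequal-variance) t-test on the transformed replicates — the simplest
defensible volcano standard, isolated in one function so a
moderated-variance test could replace it; Benjamini–Hochberg adjustment is
applied across all proteins. If both groups have zero variance the p-value
is 1 when means agree and 0 otherwise. Set-level fold change is
2^mean(log2FC) over the member proteins, i.e. the geometric mean fold —
appropriate on a multiplicative scale and insensitive to which member is
largest. Volcano rows flag |log2FC| ≥ 0.5 and q ≤ 0.05 by default.

## Synthetic cohorts

The generator produces the structure the analysis assumes, so every stage
is testable offline:

* **Correlation structure.** One latent Gaussian factor per module;
  protein i in module m has latent value √w·f_m + √(1−w)·ε. Because
  Spearman depends only on the copula, w is calibrated from the target
  rank correlation ρ_S via the bivariate-normal relation
  ρ_S = (6/π)·arcsin(ρ_P/2), giving w = 2·sin(π·ρ_S/6). Background
  proteins are independent.
* **Intensities.** exp(loc_i + scale_i·latent), loc ~ U(4, 10) and
  scale ~ U(0.5, 1.5) on the natural-log scale — log-normal intensities
  spanning ~4 decades, a realistic dynamic range for label-free
  quantification.
* **Missingness.** Uniform (each cell missing with fixed probability, for
  null tests) or detection-limit-like (detection probability a logistic
  function of ln intensity with a floor and steepness), reflecting that
  real sparsity is intensity-driven. Default benchmark cohorts use 10%
  uniform missingness.
* **Annotations.** One term per planted module plus random decoy terms
  (default 50 decoys of size 8); lethal pairs drawn 80% within modules.
* **Depletion experiments.** Per-protein baseline log2 intensity
  ~ U(10, 20), a planted log2(fold) shift on a member set in one
  condition, i.i.d. N(0, sd) replicate noise on the log2 scale
  (default sd 0.2, the scale of replicate scatter in chromosome-proteomics
  data), exponentiated back to intensities.

All randomness flows through a single seeded numpy PCG64 generator; the
same spec and seed reproduce outputs byte-identically.

**What the generator does not emulate:** batch effects, TMT ratio
compression, correlated (structured) missingness across samples,
peptide-level quantification noise, or shared-peptide ambiguity between
protein groups. Passing tests therefore demonstrate that the statistics
recover planted structure under idealized sampling, not that any specific
biological claim about a real dataset is correct.

## Benchmark conditions and problem sizes

The acceptance surface runs on cohorts of 10 modules × 8 proteins at
target within-module ρ_S = 0.7, 200 background proteins, 300 samples, 10%
uniform missingness, 20 independent seeds — large enough that module
recovery and shift statistics stabilize, small enough to regenerate from
scratch in seconds. Depletion benchmarks plant a 1.74-fold change on a
6-protein set over 4+4 replicates (noise sd 0.2), with fold recovery
measured over 200 seeds and type-I calibration over 2000 null proteins.
Note that with 10 signal terms among 60, the term-median shift is positive
in expectation (~+0.003) but its per-seed sign has roughly a 7% chance of
flipping; it is the weakest-powered statistic in the suite by design,
since only a sixth of its terms carry signal.

## Known limitations

* Zero imputation interacts with ties: for partially missing vectors
  Spearman is no longer invariant to monotone transforms applied before
  imputation, because the imputed zeros tie at the bottom of the ranking.
  The pipeline correlates the imputed values as given and does not try to
  undo this.
* The square-TSV round trip cannot distinguish a true off-diagonal 0 from
  an undefined entry; on re-read, only all-zero diagonal rows are marked
  undefined. The long-format export carries the `defined` flag explicitly.
* The Welch t-test with 4+4 replicates is conservative for proteins with
  very small within-group variance; no empirical-Bayes moderation is
  applied in this version.
* Annotation terms are flat sets; no ontology-graph (ancestor closure)
  reasoning is performed.
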