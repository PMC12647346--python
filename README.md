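# gbacorr

Guilt-by-association (GBA) analysis of proteome co-abundance. Given a wide
protein-abundance matrix (proteins × samples, as produced by pan-cancer
cell-line or patient-cohort proteomics), the package asks: *which proteins
co-vary with a protein of interest across hundreds of samples?* Correlated
abundance across many conditions is evidence of shared pathway membership —
the rationale that placed cohesin subunits among the top correlators of the
centromere protein CENP-C in published pan-cancer datasets.

It is written for proteomics and systems-biology researchers who want to
run ranked correlation queries against their own (or public) abundance
tables, and to validate that the correlation structure of a dataset is
biologically coherent before trusting any single query.

## Method

1. **Zero imputation.** Missing cells (undetected proteins) are imputed as
   0 — an undetected protein is treated as absent, not unknown.
2. **All-vs-all Spearman.** The correlation matrix ρ is the Spearman rank
   correlation of every protein pair across samples (average ranks for
   ties). Undefined correlations (constant rank vectors, typically
   never-detected proteins) are stored as 0, with a mask preserving the
   distinction.
3. **Ranked queries.** For a bait protein *b*, all N proteins are ranked by
   ρ(b, ·) in descending order — no significance cutoff; the output is a
   position such as "rank 729 of 15,312".
4. **Validation statistics.** Per-annotation-term median of within-term
   pair correlations (values exactly 1 excluded) and the median correlation
   of curated synthetic-lethal pairs, each contrasted against the dataset
   background median of all correlations.
5. **Panel summaries.** For a named panel (e.g. CCAN + NDC80 complex):
   correlation submatrix, per-protein correlation and abundance quartiles,
   and detection sparsity.
6. **Depletion contrast.** Two-condition replicate experiments: per-protein
   log2 fold change on log2(x + pseudo) intensities, Welch t-test,
   Benjamini–Hochberg adjustment, and geometric-mean fold change over a
   protein set (2^mean(log2FC)).

A synthetic-cohort generator (Gaussian-copula latent factors, log-normal
intensities, abundance-dependent or uniform missingness, module-aligned
annotation terms, planted fold changes) makes the whole pipeline testable
without downloading any external dataset.

## Worked example

```python
import gbacorr as g

matrix, terms, pairs, truth = g.generate_cohort(g.CohortSpec(seed=42))
c = g.spearman_matrix(matrix)              # zero-imputes, then correlates

bait = truth.modules["MOD000"][0]
r = g.rank_partners(c, bait)
for row in g.top_k_table(r, 10, highlight={"module": set(truth.modules["MOD000"])}):
    print(f"{row['rank']:>4}  {row['partner']}  {row['rho']:+.3f}  {row['highlight']}")

s = g.term_median_distribution(c, terms)
print(f"shift {s.shift:+.4f}")

e, members = g.generate_depletion(100, 6, 1.74, n_reps=4, noise_sd=0.2, seed=42)
fold, _ = g.set_fold_change(g.differential_abundance(e), members)
print(f"planted-set fold change: {fold:.3f}")
```

prints

```
   1  P0000  +1.000  module
   2  P0003  +0.467  module
   3  P0007  +0.457  module
   4  P0006  +0.442  module
   5  P0001  +0.436  module
   6  P0005  +0.429  module
   7  P0002  +0.422  module
   8  P0004  +0.382  module
   9  P0038  +0.133
  10  P0127  +0.131
shift +0.0036
planted-set fold change: 1.786
```

The bait heads its own table (ρ = 1); all 7 of its module co-members fill
the next ranks, well separated from the background (ρ ≈ 0.13). Note the
realized within-module Spearman (~0.45) sits below the generator's 0.7
target because 10% of cells are missing and zero-imputed — the same
attenuation a real sparse dataset shows. The term-median shift is positive
(coherent annotation terms correlate above background), and the planted
1.74-fold depletion signature is recovered as 1.79 from 4+4 noisy
replicates.

The same stages are available from a shell:

```sh
gba simulate --seed 42 --out cohort/
gba correlate --abundance cohort/abundance.tsv --out corr.tsv
gba query --matrix corr.tsv --bait P0000 --top 25 --out top.tsv
gba go-validate --matrix corr.tsv --terms cohort/terms.tsv --out go/
gba sl-validate --matrix corr.tsv --pairs cohort/pairs.csv --out sl/
gba depletion --experiment reps.tsv --set members.txt --out dep/
gba run --config pipeline.yaml      # multi-stage run with a manifest
```

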