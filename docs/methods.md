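# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind `metadiet`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Pipeline model and assumptions

The pipeline ingests one integer count table per metabarcoding marker
(PCR replicates × MOTUs) plus a replicate→sample map and per-sample
metadata, and assumes:

* replicates of one sample are technical repeats of the same DNA extract,
  so their relative-abundance profiles estimate the same composition;
* read depth carries no biological signal — all distance and averaging
  operations work on row-normalized profiles, never raw counts;
* taxonomic annotations (lineage, dietary category, plant functional
  group) are given per MOTU and are correct; the pipeline restricts but
  does not re-assign taxonomy;
* the broad-range eukaryote marker is an unbiased estimator of the
  *category-level* diet composition, while specialized markers are trusted
  only for *within-category* relative abundances. This is the central
  assumption of marker fusion and it is untestable from the data itself;
  fusion therefore conserves category mass exactly and records any
  specialized-marker detection that lacks scaffold support as
  occurrence-only evidence rather than inventing abundance for it.

Stage order is fixed: run merging → global MOTU filter → replicate QC →
replicate averaging → per-sample 1% filter → taxonomic scope → fusion →
metrics → statistics. The only genuinely ambiguous ordering (1% filter
before vs after replicate averaging) defaults to *after* averaging, the
position consistent with the filter's tag-jump purpose: averaging first
dilutes a jump event across replicates, making the per-sample threshold a
test of the sample-level composition the later stages actually consume.

## Replicate QC: the dw/db threshold

For each marker table, dw is the Euclidean distance of each replicate's
profile to the unweighted mean profile of its sample; db is the set of
pairwise Euclidean distances between sample mean profiles. The rejection
threshold is the intersection of the two distributions, estimated as:
Gaussian KDEs with Silverman bandwidth evaluated on a 512-point grid over
[0, max(db)], taking the smallest grid point past the dw mode where the dw
density falls below the db density. Degenerate shapes have closed-form
fallbacks: all-equal dw returns that value plus half the gap to min(db);
non-crossing densities return the midpoint of max(dw) and min(db).

Removal uses strict inequality (dw > threshold; ties kept) and is batched
per iteration; sample means, db and the threshold are recomputed each
iteration from survivors until a pass removes nothing (a fixpoint) or
`max_iter` (default 20) is hit. Samples reduced to a single replicate stay
in the analysis (their dw is 0 thereafter); samples losing every replicate
are reported, not silently dropped. Zero-read replicates are excluded
before distances are formed. Control replicates are never subject to the
filter. The KDE-crossing estimator and the batch-removal convention are
design choices — the underlying idea fixes only "the intersection of the
dw and db distributions", not an estimator.

## Filters

* Global: drop MOTUs with sequence length < 10 bp, or with dataset-wide
  total reads ≤ 10 (boundary semantics: 10 bp kept, 10 reads dropped).
  Order-independent in its two criteria and idempotent.
* Per-sample 1%: zero entries below 0.01 within a sample, drop all-zero
  columns, renormalize rows. Emptied samples are retained as flagged zero
  rows for bookkeeping. Idempotent because every surviving entry is ≥ the
  threshold after renormalization.
* Scope: keep MOTUs whose lineage contains any of the marker's target
  clades; MOTUs without lineage are out of scope. Rows are renormalized
  afterwards.
* Controls are advisory: the screen reports per-MOTU read shares in
  control replicates, flags dietary MOTUs above 1% in any negative
  control, and verifies positive-control recovery. Nothing is subtracted,
  since control information tracks contamination rather than measuring a
  correctable rate per MOTU.

## Metrics

wPOO uses the strict >1% occurrence rule; a sample with k occurring taxa
gives each 1/k, and samples with zero occurrences are excluded from the
across-sample mean (wPOO then still sums to 1 over taxa). Hill numbers use
the analytic q→1 limit exp(−Σ p ln p) rather than a numeric limit, ignore
zero entries, and are reported both over all fused taxa and over the
genus-identified subset (renormalized). Aggregation (category, functional
group, genus) sums member proportions and so commutes with row
normalization.

## Statistics

All composition tests operate on Hellinger-transformed rows, making
Euclidean machinery equivalent to Hellinger distance on compositions.

* PERMANOVA: sequential (Type-I) sums of squares over an ordered term
  list, computed by incremental orthogonal projections (SVD-based, rank
  tolerant, so R² partitions are invariant to factor-level relabelling and
  collinear codings lose only redundant directions). Pseudo-F per term
  uses the residual mean square; the null permutes response rows (within
  strata when given); p = (1 + #{F* ≥ F}) / (1 + n_perm) — the add-one
  estimator, which cannot report p = 0. Observed infinite F (zero residual)
  counts permuted infinite F as ties. A response with (numerically) zero
  total variance yields a flagged degenerate result with p = 1.
* The univariate permutation ANOVA is the same machinery on a one-column
  response and reproduces the classical F statistic exactly.
* PCA: column-centered SVD; eigenvalues are squared singular values /
  (n−1); axes below numerical rank are dropped.
* RDA: predictors treatment-coded (alphabetically first level as
  reference; interactions as products of main-effect codes), centered, and
  — for partial RDA — residualized on the condition design along with the
  response. The decomposition is the PCA of the fitted values;
  adjusted R² = 1 − (1 − R²)(n − 1)/(n − m − 1) with m the number of
  linearly independent coded predictor columns. With no usable predictor
  columns the result degrades to the PCA of the (conditioned) matrix,
  which also serves as the intercept-only consistency check. A conditioned
  matrix with no variance left is flagged degenerate rather than reporting
  a ratio of rounding noise.
* Default per-species models mirror a two-factor field design: phase +
  season (+ interaction when every cell has ≥ 2 samples); the RDA uses the
  phase×season interaction as a single four-level factor with sampling
  site partialled out when the design supports it, otherwise additive
  terms.

## Synthetic-data generator

What it emulates: the post-clustering stage of a two-species (bank/tundra
vole), two-season, two-phase faecal metabarcoding study with five markers —
Sper01 (*trn*L, seed plants), Bryo01 (*trn*L, bryophytes), Euka02 (18S,
all eukaryotes; the fusion scaffold), Fung01 (ITS1, mushrooms + lichens)
and a COI arthropod marker — with triplicate PCRs for Sper01/Euka02 and
duplicates otherwise, and one PCR negative + one PCR positive control per
marker.

Generative model and defaults (units in parentheses):

| parameter | default | meaning |
|---|---|---|
| `n_per_cell` | 8 | samples per species × phase × season cell (128 total) |
| `taxa_per_category` | 40/8/10/6/6 | plant/bryophyte/arthropod/lichen/mushroom pool |
| `base_alpha` | 0.3 | within-category Dirichlet sparsity of each species base |
| `diet_concentration` | 12 | Dirichlet concentration of samples around the base |
| `phase_effect`, `season_effect` | 2.0 | multiplier on affected taxa (crash phase / winter) |
| `effect_fraction` | 0.2 | fraction of taxa an effect touches |
| `reads_mean` | 2000 | mean replicate depth (gamma-Poisson, dispersion 0.15) |
| `replicate_concentration` | 100 | Dirichlet-multinomial φ (replicate overdispersion) |
| `tag_jump_rate` | 0.005 | per-read probability of moving to another replicate |
| `outlier_replicate_rate` | 0.02 | probability a replicate's profile is swapped |
| `replicate_failure_rate` | 0.02 | probability of a zero-read replicate |
| `marker_bias_sd` | 0.25 | lognormal σ of per-taxon detection bias |

The category-level species bases make the bank vole a generalist (larger
lichen/fungal share) and the tundra vole plant-dominated; at these settings
fused diets have ^1D around 8–12 effective taxa and phase/season effects
are moderate relative to between-individual variation, matching the
qualitative structure such field studies report. Dirichlet-multinomial
replicate noise (not plain multinomial) is essential: without
overdispersion the dw/db filter problem is trivial. Tag jumps act at read
level across all replicates of a marker run, so positive-control sequence
leakage into biological replicates directly estimates the jump rate.
Outlier replicates take another random sample's marker truth, the same
failure mode (mislabelled/contaminated PCR) the dw/db filter targets.
Everything is reproducible from a single seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequence-level error (chimeras, primer
mismatch), reference-database gaps and wrong taxonomy, copy-number and
digestion biases that decouple RRA from ingested biomass, spatial or
temporal autocorrelation between samples, and true vole diets. Recovery
results (QC sensitivity ~0.95, fused-vs-truth Spearman ~0.85) certify the
algorithms, not field accuracy.

## Test and report problem sizes

The test-suite and acceptance-script simulations are sized for a laptop
run: QC recovery pools 50 spiked studies of 20
samples × 3 replicates; the PERMANOVA type-I rate uses 1000 (tests) / 400
(report) null datasets of 16 samples at 199 permutations; enumeration
oracles use n ≤ 7 where 9999 Monte-Carlo draws are compared against all
row permutations; the end-to-end determinism check uses a 104-sample
study. The fusion-fidelity correlation is computed with the per-sample 1%
filter disabled: in the artifact-free condition the filter has no tag
jumps to remove and would only truncate genuine sub-1% signal, which is a
property of the filter, not of fusion.

## Known limitations

* The dw/db threshold is a density-crossing heuristic; with very few
  samples (db sparse) it can be unstable, which is why batch removal and a
  fixpoint stop are used rather than one-at-a-time deletion.
* Fusion assigns zero abundance to categories the scaffold marker missed;
  such detections survive only in the occurrence matrix. Real studies may
  prefer a pseudo-abundance convention; the conservative choice keeps the
  fused matrix a true reallocation of scaffold mass.
* Sequential (Type-I) sums of squares make term order meaningful; users
  must order terms deliberately, as with any Type-I ANOVA.
* p-values are permutation-based and bounded below by 1/(n_perm + 1).
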