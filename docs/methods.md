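# Methods

This note documents the statistical procedures implemented in
`periomics`, the choices made where a design was genuinely open, and what
the synthetic-data tests do and do not demonstrate.

## Data model and shared transform

All analyses operate on samples × features tables of non-negative
abundances.  Counts are closed to per-sample proportions; all-zero
samples are retained but flagged and refused by Bray–Curtis (the
dissimilarity is undefined between empty profiles) rather than silently
dropped.  The standard transform chain is: prevalence filter (keep
features reaching ≥ 0.1 % relative abundance in ≥ 1 sample) → relative →
natural `log(x + 1)` → Bray–Curtis.  The filter threshold is applied on
the relative scale regardless of the stored scale, and the filter is
idempotent.  Tables are exchanged as TSV (UTF-8, `.` decimal) so every
intermediate is diff-able.

An optional per-patient mean-collapse handles cohorts in which pooled
replicate samples of one patient were sequenced separately; it is off by
default because it is a cohort-specific correction, not part of the core
method, and when used it is applied *before* the prevalence filter is
re-run (the filter-after-averaging order is the package's choice; the
alternative order changes results only for features straddling the
threshold).

## EC feature construction

Genes annotated with several EC codes are counted at the deepest
hierarchy level at which the codes still agree: the longest common prefix
of the parsed codes.  If agreement ends before the second field, the
gene's counts go to an `Unknown` bucket — a fortiori for disagreement in
the first field.  `Unknown` also receives unannotated genes, so grand
totals are conserved exactly.  The `Unknown` bucket is kept in
relative-abundance denominators by default (configurable), on the view
that unassignable transcription is still transcription.

Taxon-resolved profiling keeps the `top_n` most abundant EC-annotated
genes (default 10⁶, automatically capped at the gene count), drops
EC-less genes first, normalises each sample by the retained total and
aggregates by (EC, taxon) at class or genus level.  Summing the tensor
over taxa reproduces the EC table restricted to the retained genes — an
exact invariant used in the tests.

## Ordination

PCoA eigendecomposes the Gower-centred matrix `G = −½ J D² J`.  Negative
eigenvalues (Bray–Curtis is non-Euclidean) are retained and reported as a
mass fraction for diagnostics but excluded from coordinates; no
Lingoes/Cailliez correction is applied, since the constrained analysis
operates on the positive-eigenvalue axes only.  nMDS delegates to SMACOF
with isotonic regression on rank-transformed dissimilarities (weak tie
treatment), best of 20 seeded random starts by Kruskal stress-1; the
dimensionality default is k = 2.

## PERMANOVA and PERMDISP

The pseudo-F uses `SS_T = (1/N) Σ_{i<j} d²_ij` and per-group within sums;
`F = [SS_A/(a−1)] / [SS_W/(N−a)]`.  The p-value is
`(1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`.  With strata, diagnosis labels
are permuted only within each patient block — the exchangeable units of a
repeated-measures design; blocks carrying a single label contribute no
permutation variability and trigger a warning.  An exact variant
enumerates all distinct relabelings for tiny two-group designs and is the
oracle for the Monte-Carlo path.

PERMDISP computes each sample's distance to its own group centroid in
positive-eigenvalue PCoA space (centroids, not spatial medians — the
simplest defensible reading, matching the centroid option of standard
implementations) and permutes those distances across samples under a
one-way ANOVA F.

## CAP

The model regresses centred group indicators on the first *m* orthonormal
PCoA axes `Q_m`; the eigenvalues of `Q_mᵀ H Q_m` (H the indicator
projection) are the squared canonical correlations δ², verified in tests
against an independent QR/SVD canonical-correlation routine to 1e-8.
*m* is selected by maximising leave-one-out allocation success over
`1..min(n−g, 30)`, ties to the smallest *m* — the standard diagnostic for
choosing the axis count.  Held-out and new samples are placed by Gower
addition, `g_new,i = −½(d²_new,i − r_i − r_new + s)`, whose axis scores
reproduce a duplicated training point exactly; allocation is to the
nearest group centroid in canonical space with lexicographic tie-break
(flagged).  CAP1 is oriented so the healthy centroid scores negative,
making positive feature–CAP1 correlations disease-associated; the
reference group is configurable.  Feature correlations are Spearman; a
constant feature has no defined rank correlation and is reported as r = 0
with an `undefined` flag.

## Differential selection

Mann–Whitney U is exact (full enumeration) when the smaller group has ≤ 8
observations and the pooled data are tie-free, otherwise the normal
approximation with tie correction.  BH q-values are reported alongside,
but the volcano rule uses the **raw** p: a feature is selected iff
`|r_CAP1| > 0.4` (strict) and `p ≤ 0.001` (inclusive).  Cohen's d uses
the pooled n−1 standard deviation; a zero pooled SD yields ±∞/NaN flags,
never a clipped number.

## Pathway readouts

Pathway definitions (amino acid × anabolic/catabolic → EC4 set) are
consumed from TSV.  Per sample: *abundance* is the summed relative
abundance of the pathway's ECs; *coverage* is the fraction of the
pathway's ECs at or above τ, where τ is a single global median over all
(EC, sample) entries of the full post-filter table — zeros included, both
choices exposed as switches; *expressing-taxa proportion* counts taxa
with ≥ 1 read summed over pathway ECs among taxa detected in that sample
(per-sample detection is the default reading; all-taxa denominators are a
switch).

## Ecology folds

For each (taxon, amino acid, direction) and scope (pooled or per
diagnosis group — the default, matching the health/disease framing of the
network figures), shares are computed on expression summed over the
scope's samples: `φ = log2(specific_share / total_share)`.  Folds are
computed on within-scope sums rather than per sample and averaged, which
is the stabler estimator at these depths.  No pseudocount is added: a
zero share makes φ undefined and flagged.  Roles require strictly
|φ| > 1.5; low-catabolism is deliberately not emitted.

## Random-forest biomarkers

Blocks are pre-selected by `|r_CAP1| > 0.4` on the full dataset before
cross-validation — faithful to common biomarker practice but optimistic,
since selection sees all labels; the provenance records the cutoff and a
nested scheme can be built by calling the assembly inside an outer loop.
Forests fix 500 trees; features-per-split and minimum leaf size come from
a seeded random grid of 10 candidates scored by inner 5-fold AUC.
Performance is the mean over 20 repeats of stratified 10-fold CV of the
AUC of pooled out-of-fold probabilities, plus LOOCV accuracy.  RFE drops
the 10 least-important features per iteration (full-data importances),
records the CV metric per subset size, and returns the smallest size
within numerical tolerance of the best metric.  Patient-level fold
blocking is available as an opt-in switch but off by default, as the
standard workflow does not state it.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not sequencing reads:

* **Design** — 24 patients, each contributing one healthy and one
  peri-implantitis sample (48 samples, 24 + 24).  Pairing within patient
  is what makes strata-restricted permutation meaningfully different from
  free permutation.  Patient effects are shared log-normal perturbations
  (σ = 0.4) across a patient's two samples.
* **DNA** — 150 species from a log-normal base community (σ = 1.5),
  counts by Dirichlet-multinomial (concentration 300 × proportions,
  depth 15,000).  Ten planted disease-associated species receive ±4-fold
  effects; they are drawn from the above-median abundance fraction,
  because disease-associated taxa are detectable community members, not
  log-normal-tail singletons.
* **RNA** — 12 taxon classes with log-normal activities crossed with a
  sparse taxon × EC profile over 100 pathway ECs (10 amino acids ×
  anabolic/catabolic × 5 ECs, disjoint) plus 100 housekeeping ECs
  up-weighted 4×, reflecting that core expression dominates a
  transcriptome and pathway shifts barely move the compositional
  denominator.  Eight pathways are shifted ±4-fold in disease; four
  taxon-role plants solve for the pathway expression that makes the
  taxon's expected pathway share exactly 2^±2.5 × its biofilm share
  (planted taxa are set below the community median activity, since a
  dominant taxon cannot exceed its own share by a large factor).  Counts
  are Dirichlet-multinomial at depth 200,000; the gene-level view assigns
  one single-EC gene per expressed (taxon, EC) pair so the tensor
  marginal and the gene→EC aggregation agree exactly.
* **Truth** — realised species effects, shifted ECs and role edges are
  serialised with every cohort; `truth_check` scores precision/recall.

Read depths and community sizes are desk-scale stand-ins for sequencing
reality (tens of millions of RNA reads, hundreds of taxa); they preserve
the noise regime relevant to the statistics (relative abundances around
10⁻³–10⁻¹ with overdispersed counts).  What passing tests show: the
pipeline recovers planted multiplicative effects of the stated sizes
under log-normal patient and community heterogeneity and
Dirichlet-multinomial noise.  What they do not show: robustness to
compositional artefacts from unbalanced total-load shifts, tree-structured
taxon correlations, batch effects, or annotation error — none of which
the generator models.

## Numerical choices

Eigenvalue positivity tolerance 1e-10 (relative) in CAP, 1e-8 in PCoA
coordinate selection; centroid-allocation ties at 1e-12; RFE metric ties
at 1e-12 resolve to the smaller subset; relative-scale rows must sum to
1 ± 1e-9.  All stage seeds derive from one root seed via a single
`numpy` Generator, which makes every stochastic output byte-reproducible.

## Known limitations

Single-factor PERMANOVA only (no multi-factor designs or post-hoc
pairwise tests); CAP significance is delegated to PERMANOVA rather than a
trace permutation test; cross-cohort prediction assumes the caller has
harmonised feature sets between platforms; the pathway database is
consumed, not derived — curation quality is the caller's responsibility.
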