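# Methods

This note documents the models and procedures mirlink implements, the
parameters that matter, the numerical choices, and what the synthetic
generators do and do not emulate.

## Ontology and semantic similarity

The ontology is a single-namespace DAG of is_a edges (child → parent),
one root, obsolete terms dropped. Only is_a relations are used;
part_of and other relations are ignored as the conservative core of
the hierarchy.

Information content is **structural**: with `n_t` the number of a
term's descendants plus itself and `N` the number of terms in the
namespace, `p(t) = n_t / N` and `IC(t) = −ln p(t)`. The natural
logarithm is used; since only IC ratios enter the Lin measure, the base
cancels and the choice is cosmetic. "Descendants" is transitive — a
direct-children-only reading would leave `p(root) < 1` and a non-zero
root IC, breaking the normalisation. Multiple inheritance is handled by
counting distinct descendants once.

Lin similarity is `2·IC(MICA)/(IC(t1)+IC(t2))`, where the MICA is the
common ancestor (terms count as their own ancestors) with maximal IC.
IC ties between candidate MICAs cannot change the score; the
lexicographically smallest is reported for determinism. The degenerate
root pair (IC sum 0) is defined as 1 for identical terms, 0 otherwise.

Set similarity is the best-match average of the pairwise Lin matrix:
`(Σ row maxima + Σ column maxima) / (|S1| + |S2|)`, symmetric and in
[0, 1]. Empty sets are an error rather than a zero: an entity with no
enriched terms carries no functional information and is dropped
upstream (with a log message) instead of contributing fake zeros to the
score distribution.

## Differential expression

Three callers, chosen by design:

* **SAM-style** (replicated two-class designs): unpaired d-statistic
  `d_g = (mean_t − mean_c)/(s_g + s0)` with `s0` the median of the
  gene-wise pooled standard errors. The null is built from seeded
  class-label permutations (default 100). The estimated FDR at each
  |d| threshold is the permutation **median** false-call count times an
  estimated null fraction π₀ (share of observed d inside the permuted
  interquartile range), divided by the observed call count, made
  monotone by a step-up pass; the largest gene list at or below the FDR
  cutoff is returned, split by sign. Median count and π₀ are the
  conventions of the original SAM procedure; with a mean count and no
  π₀ the estimator is noticeably conservative at small effect sizes.
* **Fold change** (singleton-class or double-channel designs): per
  sample, up if the treatment/control ratio ≥ 2, down if ≤ ½
  (double-channel columns are already ratios). A gene is called only if
  one direction holds in strictly more than half of the samples where a
  ratio was computable — samples with a non-positive control value are
  excluded from both numerator and denominator. Ties fail.
* **Amplitude**: `A = (t − c)/(½(t + c))` with t, c the linear-scale
  treatment and matched-control means; A > 2/3 is up, A < −2/3 down
  (|A| = 2/3 ⇔ exactly 2-fold). Probes with t = c = 0 are skipped and
  counted.

All ratio/amplitude arithmetic presumes a linear scale; profiles carry
an `is_log2` flag and are unlogged first. Cross-dataset combination
keeps a gene iff the same direction was called in ≥ `min_support`
(default 2) datasets; genes qualifying in both directions are
discarded. Every signature maintains up ∩ down = ∅.

## Enrichment

One-sided hypergeometric upper tail `P(X ≥ k)` per term (equivalent to
one-sided Fisher on the 2×2 table). Annotations follow the true-path
rule (propagated to ancestors). The elim procedure processes terms by
decreasing longest-path depth (ties lexicographic — sibling order
cannot affect ancestors); when a term's p < α its propagated genes are
removed from every proper ancestor's annotation set before those are
tested. The pruning threshold equals the reporting threshold
(α = 0.01 by default). The background universe defaults to all
annotated genes and is overridable. No multiple-testing correction is
applied inside enrichment; the raw p < 0.01 profile is the entity's
functional fingerprint. Note elim's output is not a subset of classic
Fisher's: pruning can only raise ancestors' p-values, and terms with no
significant descendant match classic Fisher exactly (asserted in
tests).

## Association network

All small molecule × miRNA BMA scores are pooled; a normal distribution
is moment-matched (sample mean, sd with n−1) and the association cutoff
is the upper one-sided quantile `μ + z(1−α)·σ`. With the distribution
parameters μ = 0.4882, σ = 0.0965 and α = 0.01 this arithmetic yields
0.7127. Edges use score ≥ cutoff (closed boundary, so a score exactly
at the cutoff qualifies). Auxiliary scores: Meet/Min overlap
`|A∩B|/min(|A|,|B|)`, Tanimoto on user-supplied binary fingerprints
(no structure perception — fingerprints are inputs), ≥ 2-algorithm
consensus voting for miRNA targets, and Spearman rank correlation
(mid-ranks for ties) between shared-target counts and edge scores,
reported as undefined below 3 usable edges or with constant values.

## Evaluation

For each gold pair, `n_perm` (default 99) random term sets of the
miRNA's profile size are drawn without replacement — by default from
the union of all enriched terms across entities, configurable to the
full DAG — and rescored against the small molecule's true terms. Each
pair uses sub-seed `seed + i`, so results are reproducible and pairs
are independent. AUC is the Mann–Whitney U over positive–negative
comparisons with half credit for ties, which equals the trapezoidal
area under the threshold-sweep curve; the curve itself is produced by
scikit-learn and the equality is asserted in tests.

## Repositioning

Hypergeometric upper tail on the shared-miRNA count, universe
defaulting to the union of network miRNAs and disease-map miRNAs
(configurable). Pairs sharing no miRNA are excluded from the test
family by default (they are non-candidates; a flag includes them, which
changes the BH family size m). FDR control is Benjamini–Hochberg.

## Survival

Expression is log2(x+1)-transformed and z-scored per miRNA before
K-means (a `raw` flag skips this); K-means uses K = 2, Euclidean
distance, best of 10 seeded restarts. Clusters are renamed good/poor by
Kaplan–Meier ordering using the **restricted mean survival** (area
under the KM curve) over the common follow-up span: a single-point
comparison at the last common time is unstable when both curves are
near zero in the tail, whereas the whole-curve ordering agrees with it
wherever the point comparison is clear-cut. The log-rank test is the
standard two-group 1-df chi-square (via lifelines); cohorts with no
observed events return NaN, flagged rather than fabricated. Group fold
changes are ratios of raw-scale group means, good over poor. The module
is agnostic to time units.

## Synthetic data

Generators are pure functions of (parameters, seed); regeneration is
bit-identical.

* `make_dag`: random single-root is_a DAG; each term attaches to an
  earlier term (acyclic by construction), ~10% get a second parent.
* `make_expression`: log2 baselines uniform on [5, 10], Gaussian noise
  (sd 0.25), planted genes shifted by `effect` × sd (default 3σ) in
  treatment; 5-vs-5 by default, singleton designs supported.
* `make_association_scenario`: defaults of 300 terms, 12 enriched terms
  per entity, 20 small molecules × 10 miRNAs, 5 planted pairs sharing
  80% of terms. Sizes were fixed once so that planted pairs separate
  cleanly from the background score distribution while the whole
  scenario builds in under a second.
* `make_survival`: exponential event times (baseline hazard 0.1/time
  unit; the poor group's hazard is multiplied by the hazard ratio),
  exponential censoring tuned to a target censoring fraction, and
  group-shifted Gaussian miRNA expression.
* `make_pipeline_scenario`: a gene-level variant where each term owns
  private genes and an entity's planted DE genes are the genes of its
  term set, so the full file-driven path (DE → enrichment → similarity)
  can be exercised from raw matrices.

What the generators do **not** emulate: probe-level artefacts, batch
structure, platform effects, correlated noise between genes,
annotation incompleteness, and the heavy-tailed score distributions of
real compendia. Passing tests on these fixtures demonstrates the
machinery is correct and calibrated under its stated model; it does not
certify performance on real GEO/cMap-scale data, where effect sizes and
annotation quality differ.

## Numerical choices and degenerate inputs

* Hypergeometric tails via `scipy.stats.hypergeom.sf(k−1, M, K, n)`;
  tests pin them to an exact-fraction summation oracle at 1e−12.
* Zero-variance score sets cannot be threshold-fitted (error), and
  all-identical patient rows cannot be clustered (error).
* Normal-fit alpha is restricted to (0, 0.5): the cutoff must sit in
  the upper tail.
* Seeds: every stochastic routine takes an explicit seed; the pipeline
  seeds SAM permutations and ROC permutations from the run seed.

## Known limitations

* The SAM caller is a two-class unpaired reimplementation at desk
  scale, not a feature-complete SAM (no paired/multiclass designs, no
  delta-grid output).
* elim's internal threshold is tied to the reporting threshold; other
  topGO variants (weight, weight01) are out of scope.
* Tanimoto similarity requires precomputed fingerprints; no chemistry
  is perceived from structures.
* The repositioning universe choice materially changes p-values; the
  default is declared and overridable, but no attempt is made to infer
  the "right" universe from data.
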