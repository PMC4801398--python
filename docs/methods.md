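# Methods

This note records the model underlying each pipeline stage, the
parameters that matter, the numerical choices, and what the synthetic
cohorts do and do not establish.

## T-cell response classes

The response readout is the percentage of gp33-specific (tetramer+)
CD8+ T cells per mouse at days 5, 7 and 10 after immunization. Per mouse
the maximum over available days is kept; per group the mouse peaks are
averaged; per experiment the group mean is divided by the mean of the
internal rAd reference group measured in parallel. When a vector appears
in several experiments, the per-experiment ratios are averaged *after*
normalization (ratio first, then mean — the order is a package decision,
flagged in the output via `n_experiments`). Classes come from
agglomerative clustering of the ratios with Euclidean distance and the
Ward.D2 (Murtagh–Legendre) recurrence — scipy's `ward` linkage on raw
observations — cut at k = 3; the cluster with the lowest mean ratio is
"Weak", all others "Strong". Degenerate cuts (fewer than k distinct
clusters, or a tie between the two lowest cluster means) are refused
rather than broken silently.

## Preprocessing

Order: quantile normalization → log2 → detection filter → symbol
collapse (order of normalization vs. filtering is configurable). Quantile
normalization maps each column onto the across-column mean of order
statistics through average ranks, so ties receive the mean of the
quantiles they span; exact multiset equality across columns and
idempotence therefore hold for tie-free columns. Non-positive values are
floored at the smallest positive matrix value (fallback 1e-3) before
log2. A probe is kept iff its detection p ≤ 0.05 (boundary inclusive) in
at least one sample. Multi-probe genes collapse to the max-mean probe,
ties broken by probe name for determinism.

## ICA signatures

Expression is modelled as a mixture of latent gene programs,
`Y = X W` with components estimated by FastICA (logcosh contrast,
unit-variance whitening, tolerance 1e-6) on genes-as-observations, so a
component is a gene-contribution profile. Negentropy is monitored through
the logcosh surrogate `(E[G(y)] − E[G(z)])²` rather than exact entropy —
the quantity the fixed-point algorithm itself maximizes. Per component
both tails beyond |z| = 3 standardized contribution are emitted as
signatures (both tails, so the component sign indeterminacy is
irrelevant); signatures with fewer than 7 detected genes are ignored.
`n_components` defaults to `min(n_samples − 1, 6)`; the simulation
studies fix it to 3, matched to the planted latent rank, because a
component chasing a pure-noise direction breaks fixed-point convergence
at 8 samples.

Convergence policy: non-converged fits are retried with fresh restart
seeds (default 4 attempts) and then rejected. On the pipeline path an
optional tolerance annealing (decade steps up to `fallback_tol`, default
1e-3, recorded as `tol_used`) rescues the occasional dataset whose fixed
point cycles with ~1e-4 amplitude forever — a finite-sample phenomenon
at 8 samples, not a model failure; the annealed solutions differ
negligibly in the extracted tails.

Random *decoy* gene sets stand in for large external gene-set
collections whose role is to stabilize enrichment-score normalization;
they pre-warm the per-size permutation nulls and never enter the
feature space or output profiles.

## Moderated t and pre-ranked GSEA

Differential expression per bootstrap uses the empirical-Bayes moderated
t: gene variances (d_g = n_v + n_c − 2 degrees of freedom) are shrunk
toward a scaled-F prior (d0, s0²) fitted by moment-matching of
log-variances (digamma/trigamma equations, Newton-inverted trigamma; the
infinite-d0 branch uses the arithmetic mean of variances, and exact-zero
variances are offset to 1e-5 of the median). d0 → 0 recovers the
ordinary two-sample t exactly. The implementation is checked in the test
suite against an independently coded oracle and against the reference
R implementation. Degenerate bootstraps with zero within-group variance
everywhere (possible when resampling draws one pair repeatedly) fall
back to an ordinary t with a pooled floor, with a warning.

Ranked lists are sorted by decreasing t with ties broken by gene name
(stable). The enrichment score of a gene set is the extremum of the
weighted Kolmogorov–Smirnov running sum: hits add |score|^p normalized
over hits (p = 1 by default, the classic weighting; p = 0 gives the
rank-only statistic), misses subtract 1/(N − N_hits). Exact ties between
the positive and negative extremum resolve positive. Sets with no
overlap, or covering the whole list, are flagged absent. NES divides ES
by the mean of same-signed ES values of `n_perm` (default 1000) random
same-size gene sets from the ranked list's own universe; fewer than 10
same-signed permutation values triggers one doubling of the permutation
count, then an error. Null draws are seeded per (list, set size), making
profiles independent of signature evaluation order. Absent signatures
are NaN in the feature matrix and imputed 0 (the "no enrichment" value)
at training time, with a logged count.

## Random forest and voting

The classifier is a scikit-learn random forest: 2000 Gini-split trees,
mtry = ⌊√p⌋ features per split, one seed for bagging and feature
subsampling. The out-of-bag misclassification rate is recorded along a
fixed checkpoint schedule while the forest grows (warm start), giving
the error-vs-tree-count path. Importances are reported on the classical
MeanDecreaseGini scale (per-tree impurity decreases weighted by node
sample counts, averaged over trees — scikit-learn's unnormalized
importances times the training-set size); "important" signatures exceed
a threshold of 10 by convention. Per bootstrap the vote is the class
with probability > 0.5; an exact 0.5 counts as Weak (never over-call
immunogenicity), as does an exact vector-level split. The vector call is
the majority over its B bootstraps.

## Validation schemes

*Leave-one-out*: for every dataset, a forest is trained on the other
n − 1 and the left-out dataset's B bootstraps are scored. The fold's
signature database is restricted to signatures extracted from the
retained datasets. Because tail extraction is per-dataset-independent
and NES normalization uses only the ranked list's own universe, this row
subset of the full NES matrix is *exactly* the database that would be
rebuilt from the n − 1 datasets, with no leakage; `refit_signatures=False`
reproduces the laxer fixed-database variant.

*Multi-model*: M forests, each trained on one randomly chosen
representative dataset per platform; every vector's mean probability of
its expected class across models probes platform bias. Model seeds
derive from the roster content, so identical rosters give identical
models (a single-representative scheme is exactly degenerate). Rosters
that fail to span both classes — possible only at toy scales — are
redrawn.

*Cross-context*: a trained model classifies new datasets through the
identical bootstrap → rank → NES pipeline; tissue and platform tags are
metadata only. Datasets whose genes cover less than 50% (configurable)
of the signature database's gene universe are refused with a diagnostic.

## Synthetic cohorts

The generator realizes the mixture model the signature step assumes:
log2 expression = baseline + S·A + ε, with

* **S** (genes × sources): per source, a fraction `tail_fraction`
  (default 0.02) of genes in a positive tail with loadings N(+1, 0.1)
  and the same fraction in a negative tail N(−1, 0.1), disjoint across
  sources; background loadings N(0, 0.1). Mean-shifted tails (rather
  than heavy zero-mean tails) make "the planted tail" a well-defined
  gene set that a z = 3 cut can recover essentially completely; with
  fat tails the cut becomes self-defeating because the tails themselves
  inflate the component SD — hence small cohorts should raise `n_genes`,
  not `tail_fraction`.
* **A** (sources × samples): a per-vector baseline N(0, 1) plus
  pair-level activation variability with SD `activation_sd` (default 1).
  Samples form matched vector/control pairs sharing the activation
  draw; the designated immune source gains `effect_strong` (default
  2.0) or `effect_weak` (0.5) — in residual-SD units — on the vector
  half only. Pair-level activations are *variance-controlled*: when the
  pair count allows (k ≤ n_pairs − 1) the realized rows are
  symmetrically decorrelated to exact SD and zero correlation, because
  at 4 pairs raw i.i.d. draws routinely realize |corr| > 0.7 between
  sources, contradicting the independence the model is supposed to
  plant.
* **ε**: i.i.d. per-gene Gaussian noise with SD `noise_sd` (default 0.3,
  a realistic log2 technical-noise level). With `noise_sd = 0` and zero
  effect the two columns of a pair are bit-identical — an exact null.

Values are exported on the intensity scale (2^log2) together with
detection p-values (U(0, 0.04) for expressed probes, U(0.05, 1) for a
`silent_fraction` of silent probes, never overlapping planted tails), a
1:1 probe→symbol map, and per-platform gene panels (random subsets of
the stated fraction, shared across all vectors of a config). The
loading matrix and panels depend only on the config seed, so every
vector simulated under one config shares the planted immune program —
the property that makes cross-dataset signature transfer meaningful.
Tetramer kinetics: per mouse a peak day drawn from {5, 7, 10}, off-peak
days at 70% (nearer) and 40% (farther) of the peak (day 5 takes the 70%
slot when the peak is day 7), peak value = class mean (defaults 10% for
Strong and the rAd reference, 1% for Weak) times a mean-preserving
log-normal factor with CV `class_cv` (default 0.3; the between-mouse
variability is a free parameter of the generator).

Because the cohort is a matched-pairs design, the end-to-end evaluations
run the bootstrap in paired mode (drawing pairs, both members each);
the unpaired mode remains the default of `bootstrap_dataset` and is
exercised separately. The scaled-down study configuration used by the
test suite and the acceptance script is 12 vectors (6 Strong at effect
2.0× residual SD, 6 Weak at 0.5×), 4 mice per group, 1000 genes, two
platforms at 80% panel fraction, B = 25 bootstraps and 200 NES
permutations (component calibrations use 1000), sizes chosen to keep a
full run in minutes on one CPU.

What passing on these cohorts does **not** show: robustness to probe-
level array artifacts (dye bias, spatial effects), to kinetic decay of
the early transcriptional response (time points other than the assay's
are out of scope), to annotation errors in probe→gene maps, or to
biological confounders that correlate with class but not with the
planted program. The generator's class effect is homogeneous within a
class; real vectors vary in effect size, so real-data accuracy is
expected to be lower than the synthetic ceiling.

## Determinism

Every stochastic stage derives its seed as CRC32 of
(global seed | stage | dataset id | …), kept below 2³¹. Reruns of a
config are byte-identical, including the NES matrix TSV and all
predictions; this is asserted in the test suite.
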