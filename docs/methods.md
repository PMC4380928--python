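# Methods

This note documents the statistical procedures implemented in `phosphonet`,
the assumptions behind them, the defaults of the synthetic-data generator,
and the numerical choices made where the design was genuinely open.

## Screen model and hit calling

The pooled primary screen is modelled as independent per-replica Bernoulli
detection: a true bait–prey pair produces growth in each of R replicas
(default R = 4) with probability `replica_sensitivity`, any other pair with
probability `replica_fpr`. The primary-hit rule keeps pairs with growth in at
least `min_replicas` (default 2) replicas; under this model the pass rate for
true pairs is `1 − (1−s)^4 − 4s(1−s)^3` — 0.9728 at s = 0.8 — which the test
suite checks against simulation.

In the pairwise retest every kinase condition and empty-vector control is
scored in duplicate. A condition is *positive* under the default duplicate
rule when **both** duplicates grow; the permissive "any" rule is available in
every entry point. The retest protocol on which this is based reports
duplicate testing without stating an agreement rule, so the conservative
reading is the default and the choice is explicit API surface.
Classification is a partition: *independent* if any control is positive
(growth without a kinase is taken as sufficient evidence of
non-conditionality, even when kinase conditions are also positive),
*dependent* if no control but at least one kinase condition is positive,
*negative* otherwise. Baits that themselves contain a tyrosine-kinase domain
cannot strictly be called independent — their own activity may phosphorylate
the partner — so such calls carry a boolean caveat flag rather than a
separate class. A separate consistency check verifies that no kinase-dead
condition is positive for a dependent pair.

## Linear-motif scoring

A motif is a map from offsets in [−5, +5] \ {0} to allowed residue sets; the
pY anchor sits at offset 0. The site score counts satisfied constraints;
offsets beyond either terminus count as mismatches (not errors), so terminal
tyrosines remain scorable. The per-interaction statistic is the maximum over
all tyrosines of the partner and all motifs of the reader — the max over
motifs generalises cleanly to readers with two SH2 domains — with ties
broken toward the lower position, then the earlier motif in table order.
Categories collapse scores above 3 into a "3+" bin.

Class comparison uses a two-sided Wilcoxon rank-sum with midrank ties. When
the number of group assignments C(n₁+n₂, n₁) is ≤ 20,000 the permutation
distribution is enumerated completely (two-sided p = min(1, 2·min(P≤, P≥)));
larger samples use scipy's tie-corrected normal approximation. The exact
path exists because match counts are small integers with heavy ties, where
the normal approximation is least trustworthy at small n.

Motif-mediated edge prediction flags an edge iff its best site reaches
`min_match` constraints **and** is a known phospho-site. The threshold
default is 2; the publication-scale analysis behind this operation never
states its threshold, so the value is exposed in the API and no claim is
made of reproducing any particular flagged-edge count.

## Network statistics

Interaction records are collapsed to an undirected simple graph on distinct
protein pairs before any topology statistic (pair-level counting). The
degree exponent is by default the least-squares slope of log₁₀ count against
log₁₀ degree over degrees ≥ 1 with positive count — the era-typical method
for interactome studies of the era — with a continuous-approximation maximum-likelihood
alternative (`method="mle"`, k_min = smallest positive degree). With fewer
than two distinct degrees the exponent is undefined.

Reader–reader enrichment counts edges whose prey is a reader and tests the
upper tail under a binomial null (each edge draws its prey independently,
success probability = reader fraction of the prey universe; default) or a
hypergeometric null (prey drawn without replacement). The published analysis
this mirrors does not state its null, so both are exposed and the model used
travels with the result. Over-representation analysis is the standard
hypergeometric upper tail of the query/annotation overlap within a stated
universe, Bonferroni-corrected over the number of sets tested ("corrected
for the number of tests", read literally).

## Coverage estimation

Two-sample capture–recapture treats the literature-curated set and the
screen set as independent samples of a closed interaction space. The
Lincoln–Petersen estimator N̂ = n₁n₂/m requires m ≥ 1 and is exposed next to
the Chapman variant (n₁+1)(n₂+1)/(m+1) − 1, which stays defined at m = 0.
Novelty is 1 − m/n₂ and the undiscovered fraction 1 − (n₁+n₂−m)/N̂. The
estimator assumes equal catchability of every interaction in both samples —
certainly optimistic for literature curation, which oversamples
well-studied proteins — so the numbers are order-of-magnitude statements,
which is how they are used. The screen-set size 79 used in the worked
examples is the value consistent with the published ~81% novelty at 15
overlapping interactions; with n₁ = 147 it also reproduces the published
~73% undiscovered fraction, a self-consistency the tests assert.

## Kinase-profile clustering

Profile similarity is |a∩b|²/(|a|·|b|) over the kinase spots supporting each
interaction, computed after restricting to the k most frequent spots
(default 14; ties broken lexicographically; profiles emptied by the
restriction are excluded and reported). "Preference set to the median
globally" is read as the median of all off-diagonal similarities.

Affinity propagation is implemented as standard Frey–Dueck
responsibility/availability message passing with damping 0.9 (the APCluster
default of the era), up to 1,000 iterations, convergence declared when the
exemplar set is stable for 50 iterations; non-convergence returns the
best-so-far partition with a warning flag. A machine-epsilon-scale seeded
jitter breaks exact ties so degenerate block matrices converge
deterministically. After convergence exemplars are refined to maximise
within-cluster similarity and points reassigned — matching the reference
implementation in scikit-learn, against which the test suite verifies
identical partitions on random similarity matrices.

## Co-IP calling

Fold is the ratio of triplicate means; Z is the background-referenced
standardised difference using the sample (n−1) SD of the background
triplicate, background being the same firefly-tagged protein pulled down
with a non-related partner in the same run. A pair is positive when both
statistics reach their thresholds (default 2). The source protocol words the
rule both inclusively ("at least two") and strictly ("larger than two"); the
default is inclusive with a `strict` flag, and calls landing exactly on a
threshold carry a boundary annotation so the two readings stay auditable.
Zero background SD leaves Z undefined; the call then falls back to the fold
criterion and is flagged. Both statistics are ratios of readings from one
instrument, so calls are exactly invariant under unit rescaling — a property
the tests assert. The test suite also bounds the null positive rate with a
conservative Cantelli inequality on the log fold ratio.

## Synthetic-data generator

The generator emulates the study design at desk scale; its defaults are the
package's statement of the conditions under which everything is tested:

| parameter | default | rationale |
|---|---|---|
| `n_genes` / `n_readers` | 300 / 30 | ~10% reader fraction, scaled from 149 readers against a proteome-scale matrix |
| `sequence_length_mean` | 300 aa | typical protein length; Poisson lengths floored at 50 |
| `n_true_edges` | 150 | scaled from the ~630-pair published network |
| `frac_dependent` | 0.465 | the published dependent share (292 of 628) |
| `reader_reader_excess` | 5 | prey-side reader enrichment of the order observed |
| `replica_sensitivity` / `replica_fpr` | 0.8 / 10⁻⁴ | ~97% primary-hit pass rate; rare spurious growth |
| `kinase_activity` | 0.3 for each of 9 kinases | partially overlapping kinase support sets |
| `motif_plant_rate` | 0.5 | roughly the "order of 1/6 to 1/2" motif-explained regime, upper end so motif statistics have signal |
| `phospho_site_rate` | 0.1 | a minority of tyrosines carry known sites |
| `coip_effect` / `coip_cv` | 2 / 0.2 | 4-fold planted positives at realistic assay noise |
| `n_clusters` / `cluster_tightness` | 3 / 0.9 | well-separated kinase groups with 10% spot noise |

Sequences are i.i.d. uniform over the 20 residues, which keeps background
motif-match rates analytically computable (a 2-constraint single-residue
motif matches ≥ 1 position at a random tyrosine with probability
1 − (19/20)² = 0.0975, asserted empirically). Planted cluster templates are
disjoint chunks of a random plate permutation so the planted structure is
identifiable. All generators draw from one `numpy` PCG64 stream seeded from
`SimulationConfig.seed`, making every fixture byte-reproducible across
platforms.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequences have no composition bias or homology
structure; detection is independent across replicas and pairs (no plate or
pool spatial effects, no auto-activators); kinase support sets are drawn
independently per edge rather than from kinase–substrate biology; co-IP
noise is purely multiplicative log-normal with no expression-level
confounding; literature sampling in the coverage model is unbiased. Results
on synthetic data demonstrate the correctness of the statistical machinery,
not the biology.

## Problem sizes and numerics

The test suite runs the heaviest checks at fixed, documented scales chosen
as the package's own desk-scale conditions: 10⁴ random triples for the
scoring oracle, 10⁵ sites for the background-rate check, 2,000 true pairs
for the primary-hit rate, 20 seeds for each planted-recovery median, 10⁴
null pairs for the co-IP false-positive bound. Probability tails that
underflow double precision are floored at 10⁻³⁰⁰ before logging. Exact
rank-sum enumeration caps at 20,000 arrangements, beyond which the
tie-corrected asymptotic form takes over.
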