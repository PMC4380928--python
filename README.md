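# phosphonet

Analysis toolkit for **phospho-tyrosine-dependent protein–protein interaction
networks** measured with a kinase-augmented yeast two-hybrid (pY-Y2H) screen.
In such a screen, bait proteins carrying a phospho-tyrosine-recognition
domain (SH2, or a pY-binding PTB subgroup) are mated against a proteome-scale
prey matrix while a third plasmid expresses an active human tyrosine kinase;
an interaction that appears only in the presence of a kinase is
*phosphorylation dependent*. The package is aimed at interactome labs and
computational biologists who need the full downstream layer of such a study
as tested, reusable code: hit calling, dependence classification,
linear-motif statistics, network and enrichment analysis, interactome
coverage estimation, kinase-profile clustering and co-IP validation calling
— all exercisable end-to-end on synthetic data with planted ground truth.

## What it computes

* **Screen calling** — primary hits are pairs growing in ≥ 2 of the pooled
  replicas; in the pairwise duplicate retest a pair is *dependent* when at
  least one kinase condition is positive and no empty-vector control is
  (its positive kinases form the *kinase profile*), *independent* when any
  control is positive. A kinase-dead panel check flags dependent calls that
  survive inactive kinases.
* **Linear-motif statistics** — a consensus motif is a set of positional
  constraints around the pY anchor (pY-E-x-M ⇒ {+1: E, +3: M}). Each
  tyrosine *y* of a partner scores
  `s(y) = |{o : seq[y+o] ∈ allowed(o)}|`; an interaction's category is the
  maximum score over tyrosines and motifs, binned {0, 1, 2, 3+}. Classes are
  compared with a Wilcoxon rank-sum test (exact by complete enumeration for
  small groups, tie-corrected normal approximation otherwise), and edges
  whose best site reaches a match threshold *at a known phospho-site* are
  predicted as linear-motif mediated.
* **Network statistics** — giant-component structure, average degree 2E/V,
  log-log least-squares degree exponent (continuous MLE as an alternative);
  reader–reader edge enrichment with binomial or hypergeometric null;
  generic hypergeometric over-representation analysis with Bonferroni
  correction.
* **Coverage estimation** — two-sample capture–recapture: with n₁
  literature-curated and n₂ screen interactions, m overlapping, the
  Lincoln–Petersen estimate of the searchable space is `N̂ = n₁n₂/m`
  (Chapman variant for m = 0); novelty `1 − m/n₂`; undiscovered fraction
  `1 − (n₁ + n₂ − m)/N̂`.
* **Kinase-profile clustering** — pairwise similarity
  `s(a,b) = |a∩b|²/(|a|·|b|)` over the most frequent kinase spots, clustered
  by affinity propagation (responsibility/availability message passing,
  damping 0.9, preference = median off-diagonal similarity).
* **Co-IP validation** — luminescence triplicates against a matched
  background; positive iff `fold = mean(signal)/mean(background) ≥ 2` **and**
  `Z = (mean(signal) − mean(background))/sd(background) ≥ 2`; per-class
  validation rates and kinase-induction contrasts.
* **Synthetic data** — seeded generators for every input above, with planted
  motif occurrences, reader–reader excess, dependent/independent split,
  per-replica Bernoulli detection, log-normal co-IP noise and planted
  profile clusters.

## Worked example

```python
from phosphonet import SimulationConfig, simulate_study
from phosphonet.screening import classify_interactions
from phosphonet.netstats import coverage_estimate, network_summary

study = simulate_study(SimulationConfig(seed=17))
calls = classify_interactions(study["observations"], study["retests"])
summary = network_summary([c for c in calls if c.dependence == "dependent"])
print(summary.n_edges, summary.average_degree, summary.n_edges_outside_giant_component)

est = coverage_estimate(n_literature=147, n_screen=79, overlap=15)
print(round(100 * est.novelty_fraction), round(100 * est.remaining_fraction))
```

Running `examples/04_network_statistics.py` (which does the above and more)
prints:

```
dependent network: 63 edges on 66 proteins, average degree 1.91
  6 edges outside the giant component; log-log degree slope -1.84
reader-reader edges: observed 42 vs 13.5 expected (binomial P = 1.2e-11)
coverage: interaction space ~774 pairs, 81% of the screen set novel, 73% of the space still undiscovered
```

i.e. the recovered dependent network is dominated by one connected
component, reader prey occur far in excess of the random expectation (the
planted 5× excess is detected at P ≈ 10⁻¹¹), and the capture–recapture
arithmetic on a 147/79/15 literature comparison estimates a ~774-pair
searchable space of which ~73% is still undiscovered. The other scripts in
`examples/` each demonstrate one capability (simulation, screen calling,
motif statistics, clustering, co-IP calling) and print what their numbers
mean.

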