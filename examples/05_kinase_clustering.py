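"""Cluster interactions by their kinase-plate profiles.

Each interaction's profile is the set of kinase spots that supported growth.
Profiles are restricted to the most frequent spots, pairwise similarity is
|overlap|^2 / (|a| * |b|), and affinity propagation (median preference,
damping 0.9) groups interactions supported by overlapping kinase sets.
"""

from collections import Counter

from phosphonet import SimulationConfig
from phosphonet.clustering import cluster_profiles
from phosphonet.simulate import simulate_kinase_profiles

config = SimulationConfig(seed=23, n_clusters=3, cluster_tightness=0.9)
sim = simulate_kinase_profiles(config)

# simulated profiles already live on the 31-spot plate, so no restriction is
# needed here; on real plate data, top_k=14 keeps the spots that came up most
assignment, emptied, result = cluster_profiles(sim.profiles, top_k=31)
sizes = Counter(assignment.values())
print(f"{len(sim.profiles)} profiles -> {result.n_clusters} clusters "
      f"(converged: {result.converged}, {result.n_iter} iterations)")
for exemplar, size in sizes.most_common():
    print(f"  exemplar {exemplar}: {size} interactions")
if emptied:
    print(f"  {len(emptied)} profiles excluded (empty after top-14 restriction)")

# compare against the planted clusters
agreement = sum(
    1 for a in sim.profiles for b in sim.profiles
    if a.interaction_id < b.interaction_id
    and (assignment.get(a.interaction_id) == assignment.get(b.interaction_id))
    == (sim.cluster_labels[a.interaction_id] == sim.cluster_labels[b.interaction_id])
)
pairs = len(sim.profiles) * (len(sim.profiles) - 1) // 2
print(f"pairwise agreement with planted clusters: {agreement}/{pairs} "
      f"({100 * agreement / pairs:.1f}%)")
# At tightness 0.9 the three planted kinase groups are typically recovered
# exactly; lower tightness blurs profiles into one another.
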