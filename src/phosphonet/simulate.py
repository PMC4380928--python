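"""Seeded generators for every input the pipeline consumes, with planted truth.

The generator emulates the statistical structure of a phospho-tyrosine
two-hybrid (pY-Y2H) study: a protein universe with a minority of pY readers,
a ground-truth interaction network with a tunable excess of reader-reader
edges and a tunable dependent/independent split, a pooled primary screen with
per-replica Bernoulli detection, a pairwise retest against a kinase panel with
empty-vector controls, log-normal co-IP luminescence with planted positives,
and kinase-plate profiles with planted cluster structure.

Sequences are i.i.d. uniform over the 20 standard residues, so background
motif-match rates are analytically computable (a k-constraint single-residue
motif matches >= 1 position at a random tyrosine with probability
1 - (19/20)^k). All randomness flows through a single ``numpy`` generator
created from ``config.seed``, so every fixture is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np
import yaml

from .types import (
    AMINO_ACIDS,
    CoIPMeasurement,
    InteractionRecord,
    KinaseProfileVector,
    LinearMotif,
    ProteinRecord,
    RetestMatrix,
    ScreenObservation,
)

#: The nine non-receptor tyrosine kinases screened, one per family.
DEFAULT_KINASES = ("FYN", "ABL2", "TNK1", "FRK", "FES", "PTK2", "SYK", "BMX", "JAK2")
DEFAULT_CONTROLS = ("control-1", "control-2")

#: Kinase-plate spot universe (31 non-receptor tyrosine kinase spots).
PLATE_SPOTS = tuple(f"K{i:02d}" for i in range(1, 32))

_ALPHABET = np.array(sorted(AMINO_ACIDS))


@dataclass
class SimulationConfig:
    """All tunable parameters of the synthetic study.

    Defaults are a desk-scale version of the study design: a 300-protein
    universe with 10% pY readers, 150 true edges of which 46.5% are
    kinase-dependent, four pooled-screen replicas at 0.8 per-replica
    sensitivity and 1e-4 per-replica false growth, nine kinases with two
    empty-vector controls in the retest, two-fold-squared co-IP effect at 20%
    CV, and three planted profile clusters on a 31-spot kinase plate.
    """

    seed: int = 0
    n_genes: int = 300
    n_readers: int = 30
    sequence_length_mean: float = 300.0
    motif_plant_rate: float = 0.5
    phospho_site_rate: float = 0.1
    n_true_edges: int = 150
    frac_dependent: float = 0.465
    reader_reader_excess: float = 5.0
    replica_sensitivity: float = 0.8
    replica_fpr: float = 1e-4
    n_replicas: int = 4
    kinase_activity: Mapping[str, float] = field(
        default_factory=lambda: {k: 0.3 for k in DEFAULT_KINASES}
    )
    control_conditions: tuple[str, ...] = DEFAULT_CONTROLS
    coip_effect: float = 2.0
    coip_cv: float = 0.2
    coip_base: float = 1000.0
    n_coip_negatives: int = 50
    n_clusters: int = 3
    cluster_tightness: float = 0.9
    profiles_per_cluster: int = 20
    motif_n_constraints: int = 2

    def __post_init__(self) -> None:
        probs = [
            self.motif_plant_rate, self.phospho_site_rate, self.frac_dependent,
            self.replica_sensitivity, self.replica_fpr, self.cluster_tightness,
            *self.kinase_activity.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if min(self.n_genes, self.n_readers, self.n_true_edges, self.n_replicas,
               self.n_clusters, self.profiles_per_cluster) <= 0:
            raise ValueError("counts must be positive")
        if self.n_readers > self.n_genes:
            raise ValueError("n_readers must not exceed n_genes")
        if not self.kinase_activity:
            raise ValueError("at least one kinase condition required")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "kinase_activity" in data:
            data["kinase_activity"] = dict(data["kinase_activity"])
        if "control_conditions" in data:
            data["control_conditions"] = tuple(data["control_conditions"])
        return cls(**data)


@dataclass
class SimulatedNetwork:
    """Ground-truth edges plus the positions where motifs were planted."""

    interactions: list[InteractionRecord]
    planted_sites: dict[tuple[str, str], int]


@dataclass
class SimulatedCoIP:
    """Co-IP triplicates with per-pair ground truth (True = real interaction)."""

    measurements: list[CoIPMeasurement]
    truth: dict[str, bool]


@dataclass
class SimulatedProfiles:
    """Kinase-plate profiles with their planted cluster assignment."""

    profiles: list[KinaseProfileVector]
    cluster_labels: dict[str, int]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def _random_motif(rng: np.random.Generator, reader_id: str, n_constraints: int) -> LinearMotif:
    offsets = rng.choice(
        [o for o in range(-5, 6) if o != 0], size=n_constraints, replace=False
    )
    constraints = {
        int(o): frozenset([str(rng.choice(_ALPHABET))]) for o in offsets
    }
    return LinearMotif(reader_id, f"{reader_id}_motif", constraints)


def generate_universe(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[ProteinRecord], list[LinearMotif]]:
    """Generate the protein universe and one consensus motif per reader.

    Proteins ``G0001..`` carry i.i.d. uniform sequences with Poisson-distributed
    lengths (floored at 50 residues); the first ``n_readers`` are flagged SH2
    readers. Each tyrosine is independently flagged as a known phospho-site
    with probability ``phospho_site_rate``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    proteins: list[ProteinRecord] = []
    motifs: list[LinearMotif] = []
    for i in range(config.n_genes):
        pid = f"G{i + 1:04d}"
        length = max(50, int(rng.poisson(config.sequence_length_mean)))
        seq = _random_sequence(rng, length)
        tyrosines = [p + 1 for p, aa in enumerate(seq) if aa == "Y"]
        sites = frozenset(
            p for p in tyrosines if rng.random() < config.phospho_site_rate
        )
        is_reader = i < config.n_readers
        proteins.append(
            ProteinRecord(
                pid, seq, sites,
                is_reader=is_reader,
                reader_domains=frozenset({"SH2"}) if is_reader else frozenset(),
            )
        )
        if is_reader:
            motifs.append(_random_motif(rng, pid, config.motif_n_constraints))
    return proteins, motifs


def _plant_motif(
    rng: np.random.Generator, prey: ProteinRecord, motif: LinearMotif
) -> int:
    """Write the motif (with its pY anchor) into the prey sequence in place.

    Returns the 1-based anchor position, which is also added to the prey's
    known phospho-sites.
    """
    lo = 1 + max(0, -min(motif.constraints))
    hi = len(prey.sequence) - max(0, max(motif.constraints))
    pos = int(rng.integers(lo, hi + 1))
    seq = list(prey.sequence)
    seq[pos - 1] = "Y"
    for offset, residues in motif.constraints.items():
        seq[pos - 1 + offset] = str(rng.choice(sorted(residues)))
    prey.sequence = "".join(seq)
    # re-derive site validity: planting may overwrite a previously flagged Y
    prey.phospho_sites = frozenset(
        p for p in prey.phospho_sites if prey.sequence[p - 1] == "Y"
    ) | {pos}
    prey.validate()
    return pos


def generate_truth_network(
    config: SimulationConfig,
    universe: tuple[list[ProteinRecord], list[LinearMotif]],
    rng: np.random.Generator | None = None,
) -> SimulatedNetwork:
    """Sample the planted ground-truth network.

    Baits are drawn uniformly from the readers; prey are drawn with reader
    probability inflated by ``reader_reader_excess``. A fraction
    ``frac_dependent`` of edges is kinase-dependent with a supporting kinase
    set drawn from ``kinase_activity`` (forced non-empty). With probability
    ``motif_plant_rate`` a dependent edge's prey receives the bait's full
    motif around a planted phospho-tyrosine (the prey records in ``universe``
    are updated in place).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    proteins, motifs = universe
    by_id = {p.protein_id: p for p in proteins}
    motif_by_reader = {m.reader_id: m for m in motifs}
    readers = [p.protein_id for p in proteins if p.is_reader]
    all_ids = [p.protein_id for p in proteins]
    weights = np.array(
        [config.reader_reader_excess if by_id[g].is_reader else 1.0 for g in all_ids]
    )
    kinases = sorted(config.kinase_activity)
    activities = np.array([config.kinase_activity[k] for k in kinases])

    max_pairs = len(readers) * (len(all_ids) - 1)
    if config.n_true_edges > max_pairs:
        raise ValueError("n_true_edges exceeds the number of distinct bait-prey pairs")

    interactions: list[InteractionRecord] = []
    planted: dict[tuple[str, str], int] = {}
    seen: set[tuple[str, str]] = set()
    while len(interactions) < config.n_true_edges:
        bait = readers[int(rng.integers(len(readers)))]
        w = weights.copy()
        w[all_ids.index(bait)] = 0.0  # no self-interactions
        prey = str(rng.choice(all_ids, p=w / w.sum()))
        if (bait, prey) in seen:
            continue
        seen.add((bait, prey))
        dependent = rng.random() < config.frac_dependent
        if dependent:
            support = frozenset(
                k for k, a in zip(kinases, activities) if rng.random() < a
            )
            if not support:
                support = frozenset([kinases[int(rng.choice(
                    len(kinases), p=activities / activities.sum()))]])
            rec = InteractionRecord(bait, prey, "dependent", support, "synthetic")
            if rng.random() < config.motif_plant_rate:
                planted[(bait, prey)] = _plant_motif(
                    rng, by_id[prey], motif_by_reader[bait]
                )
        else:
            rec = InteractionRecord(bait, prey, "independent", frozenset(), "synthetic")
        interactions.append(rec)
    return SimulatedNetwork(interactions, planted)


def simulate_screen(
    truth: SimulatedNetwork | list[InteractionRecord],
    universe: tuple[list[ProteinRecord], list[LinearMotif]],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ScreenObservation], list[RetestMatrix]]:
    """Simulate the pooled primary screen and the pairwise retest.

    True pairs grow per replica with probability ``replica_sensitivity``;
    every other bait-prey combination with ``replica_fpr`` (non-pairs are only
    emitted when they grew at least once). Retest matrices are produced for
    every pair passing the >= 2-replica primary rule: dependent pairs grow (per
    duplicate, at ``replica_sensitivity``) only under their supporting
    kinases and never in empty-vector controls; independent true pairs grow
    under every condition; spurious pairs grow at ``replica_fpr`` throughout.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    edges = truth.interactions if isinstance(truth, SimulatedNetwork) else truth
    proteins, _ = universe
    truth_by_pair = {e.pair: e for e in edges}
    readers = [p.protein_id for p in proteins if p.is_reader]
    all_ids = [p.protein_id for p in proteins]
    sens, fpr, R = config.replica_sensitivity, config.replica_fpr, config.n_replicas

    observations: list[ScreenObservation] = []
    for e in edges:
        growth = tuple(bool(g) for g in rng.random(R) < sens)
        observations.append(ScreenObservation(e.bait_id, e.prey_id, growth))

    # spurious growth over the rest of the bait x prey space (vectorised)
    non_pairs = [
        (b, p) for b in readers for p in all_ids
        if p != b and (b, p) not in truth_by_pair
    ]
    if non_pairs and fpr > 0:
        draws = rng.random((len(non_pairs), R)) < fpr
        for (bait, prey), row in zip(non_pairs, draws):
            if row.any():
                observations.append(ScreenObservation(bait, prey, tuple(map(bool, row))))

    kinases = sorted(config.kinase_activity)
    controls = config.control_conditions

    def duplicate(p: float) -> tuple[bool, bool]:
        return (bool(rng.random() < p), bool(rng.random() < p))

    retests: list[RetestMatrix] = []
    for obs in observations:
        if obs.growth_count < 2:
            continue
        e = truth_by_pair.get((obs.bait_id, obs.prey_id))
        conditions: dict[str, tuple[bool, bool]] = {}
        for cond in (*kinases, *controls):
            if e is None:
                conditions[cond] = duplicate(fpr)
            elif e.dependence == "dependent":
                # controls and unsupporting kinases never grow, by construction
                p = sens if cond in e.kinase_profile else 0.0
                conditions[cond] = duplicate(p)
            else:
                conditions[cond] = duplicate(sens)
        retests.append(
            RetestMatrix(obs.bait_id, obs.prey_id, conditions, frozenset(controls))
        )
    return observations, retests


def simulate_coip(
    truth: SimulatedNetwork | list[InteractionRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedCoIP:
    """Simulate luminescence co-IP triplicates for true pairs plus negatives.

    Readings are log-normal around a base level with coefficient of variation
    ``coip_cv``; true pairs' signal is multiplied by ``2 ** coip_effect``.
    ``n_coip_negatives`` non-interacting pairs are measured alongside, with
    signal distributed like background.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    edges = truth.interactions if isinstance(truth, SimulatedNetwork) else truth
    sigma = float(np.sqrt(np.log1p(config.coip_cv**2)))
    mu = float(np.log(config.coip_base)) - sigma**2 / 2  # mean-preserving

    def triplicate(scale: float = 1.0) -> tuple[float, float, float]:
        return tuple(scale * np.exp(mu + sigma * rng.standard_normal(3)))

    measurements: list[CoIPMeasurement] = []
    labels: dict[str, bool] = {}
    for e in edges:
        pid = f"{e.bait_id}:{e.prey_id}"
        measurements.append(
            CoIPMeasurement(pid, triplicate(2.0**config.coip_effect), triplicate())
        )
        labels[pid] = True
    for i in range(config.n_coip_negatives):
        pid = f"neg:{i + 1:05d}"
        measurements.append(CoIPMeasurement(pid, triplicate(), triplicate()))
        labels[pid] = False
    return SimulatedCoIP(measurements, labels)


def simulate_kinase_profiles(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedProfiles:
    """Simulate kinase-plate profiles with planted cluster structure.

    ``n_clusters`` template spot-sets are drawn as disjoint subsets of the
    31-spot plate (a random permutation split into equal chunks), so the
    planted clusters are identifiable; each profile copies its cluster's
    template with per-spot flip probability ``1 - cluster_tightness``.
    Profiles that end up empty are re-assigned their template's first spot so
    every profile has a defined similarity.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_spots = len(PLATE_SPOTS)
    if config.n_clusters > n_spots:
        raise ValueError("more clusters than plate spots")
    perm = [str(s) for s in rng.permutation(PLATE_SPOTS)]
    chunk = n_spots // config.n_clusters
    templates = [
        frozenset(perm[c * chunk : (c + 1) * chunk]) for c in range(config.n_clusters)
    ]
    flip = 1.0 - config.cluster_tightness
    profiles: list[KinaseProfileVector] = []
    labels: dict[str, int] = {}
    idx = 0
    for c, template in enumerate(templates):
        for _ in range(config.profiles_per_cluster):
            idx += 1
            spots = set()
            for s in PLATE_SPOTS:
                in_template = s in template
                if rng.random() < flip:
                    in_template = not in_template
                if in_template:
                    spots.add(s)
            if not spots:
                spots.add(sorted(template)[0])
            pid = f"I{idx:04d}"
            profiles.append(KinaseProfileVector(pid, frozenset(spots)))
            labels[pid] = c
    return SimulatedProfiles(profiles, labels)


def simulate_study(config: SimulationConfig) -> dict:
    """Run every generator off one seeded stream and return all fixtures.

    Returns a dict with keys ``proteins``, ``motifs``, ``network``,
    ``observations``, ``retests``, ``coip`` and ``profiles``.
    """
    rng = np.random.default_rng(config.seed)
    universe = generate_universe(config, rng)
    network = generate_truth_network(config, universe, rng)
    observations, retests = simulate_screen(network, universe, config, rng)
    coip = simulate_coip(network, config, rng)
    profiles = simulate_kinase_profiles(config, rng)
    return {
        "proteins": universe[0],
        "motifs": universe[1],
        "network": network,
        "observations": observations,
        "retests": retests,
        "coip": coip,
        "profiles": profiles,
    }
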