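"""Domain types for phospho-tyrosine-dependent interaction analysis.

Conventions used throughout the package:

* **Coordinates are 1-based.** A phospho-site at position ``p`` refers to the
  ``p``-th residue of the sequence (so ``sequence[p - 1]`` in Python), matching
  the way sites such as "Y68" or "Y124" are written in the literature.
* **Identifiers are gene symbols** (or any caller-chosen string key); database
  accessions, where present, travel as optional metadata and never as keys.
* Motif offsets are relative to the phospho-tyrosine anchor, which sits at
  offset 0 and is never itself a constraint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
READER_DOMAINS = frozenset({"SH2", "PTB_IRS1", "PTB_PID"})

#: Dependence labels for an interaction with respect to tyrosine-kinase activity.
DEPENDENT = "dependent"
INDEPENDENT = "independent"
DEPENDENCE_LABELS = frozenset({DEPENDENT, INDEPENDENT})

SOURCES = frozenset({"screen", "literature", "synthetic"})


@dataclass
class ProteinRecord:
    """A protein sequence with its known phospho-tyrosine positions.

    ``is_reader`` marks proteins carrying a pY-recognition fold (SH2 or a
    pY-binding PTB subgroup); ``reader_domains`` names the fold(s) and must be
    non-empty exactly when ``is_reader`` is set.
    """

    protein_id: str
    sequence: str
    phospho_sites: frozenset[int] = frozenset()
    is_reader: bool = False
    reader_domains: frozenset[str] = frozenset()
    accession: str | None = None

    def __post_init__(self) -> None:
        self.phospho_sites = frozenset(self.phospho_sites)
        self.reader_domains = frozenset(self.reader_domains)
        self.validate()

    def validate(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"record {self.protein_id!r}: non-amino-acid characters {sorted(bad)}"
            )
        for p in self.phospho_sites:
            if not 1 <= p <= len(self.sequence):
                raise ValueError(
                    f"record {self.protein_id!r}: phospho-site {p} outside sequence "
                    f"(length {len(self.sequence)})"
                )
            if self.sequence[p - 1] != "Y":
                raise ValueError(
                    f"record {self.protein_id!r}: phospho-site {p} is "
                    f"{self.sequence[p - 1]!r}, not Y"
                )
        if not self.reader_domains <= READER_DOMAINS:
            raise ValueError(
                f"record {self.protein_id!r}: unknown reader domains "
                f"{sorted(self.reader_domains - READER_DOMAINS)}"
            )
        if self.is_reader != bool(self.reader_domains):
            raise ValueError(
                f"record {self.protein_id!r}: reader_domains must be non-empty "
                "iff is_reader"
            )

    def tyrosine_positions(self) -> list[int]:
        """All 1-based tyrosine positions in the sequence."""
        return [i + 1 for i, aa in enumerate(self.sequence) if aa == "Y"]


@dataclass
class LinearMotif:
    """Positional constraints around a phospho-tyrosine for one pY reader.

    ``constraints`` maps an offset (in [-5, +5], never 0 — offset 0 is the pY
    itself) to the set of residues allowed there; unconstrained offsets are
    simply absent. The established PIK3R3 recognition motif pY-E-x-M, for
    instance, is ``{+1: {'E'}, +3: {'M'}}``.
    """

    reader_id: str
    name: str
    constraints: dict[int, frozenset[str]]

    def __post_init__(self) -> None:
        self.constraints = {o: frozenset(r) for o, r in self.constraints.items()}
        self.validate()

    def validate(self) -> None:
        if not self.constraints:
            raise ValueError(f"motif {self.name!r}: at least one constraint required")
        for offset, residues in self.constraints.items():
            if offset == 0 or not -5 <= offset <= 5:
                raise ValueError(
                    f"motif {self.name!r}: offset {offset} outside [-5, 5] \\ {{0}}"
                )
            if not residues or not residues <= AMINO_ACIDS:
                raise ValueError(
                    f"motif {self.name!r}: offset {offset} has invalid residue set "
                    f"{sorted(residues)}"
                )

    def __len__(self) -> int:
        return len(self.constraints)


@dataclass
class InteractionRecord:
    """A bait-prey interaction: one edge of the network.

    The bait is always a pY reader. ``kinase_profile`` holds the kinase
    conditions that supported the interaction and must be non-empty for
    dependent edges. ``bait_kinase_caveat`` flags baits that themselves carry a
    tyrosine-kinase domain, where independence cannot strictly be concluded.
    """

    bait_id: str
    prey_id: str
    dependence: str
    kinase_profile: frozenset[str] = frozenset()
    source: str = "screen"
    bait_kinase_caveat: bool = False

    def __post_init__(self) -> None:
        self.kinase_profile = frozenset(self.kinase_profile)
        self.validate()

    def validate(self) -> None:
        if self.dependence not in DEPENDENCE_LABELS:
            raise ValueError(f"unknown dependence label {self.dependence!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.dependence == DEPENDENT and not self.kinase_profile:
            raise ValueError(
                f"{self.bait_id}-{self.prey_id}: dependent interaction requires a "
                "non-empty kinase profile"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.bait_id, self.prey_id)


@dataclass
class ScreenObservation:
    """Per-replica growth of one bait-prey pair in the pooled primary screen."""

    bait_id: str
    prey_id: str
    replica_growth: tuple[bool, ...]

    def __post_init__(self) -> None:
        self.replica_growth = tuple(bool(g) for g in self.replica_growth)
        if len(self.replica_growth) < 1:
            raise ValueError("at least one replica required")

    @property
    def growth_count(self) -> int:
        return sum(self.replica_growth)


@dataclass
class RetestMatrix:
    """Duplicate growth per condition for one pair in the pairwise retest.

    ``conditions`` maps a condition label (a kinase, or an empty-vector
    control) to its duplicate growth calls. ``controls`` names the labels that
    are empty-vector controls; at least one must be present.
    """

    bait_id: str
    prey_id: str
    conditions: dict[str, tuple[bool, bool]]
    controls: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.conditions = {c: (bool(a), bool(b)) for c, (a, b) in self.conditions.items()}
        self.controls = frozenset(self.controls)
        self.validate()

    def validate(self) -> None:
        if not self.controls:
            raise ValueError(
                f"{self.bait_id}-{self.prey_id}: at least one empty-vector control "
                "condition required"
            )
        missing = self.controls - self.conditions.keys()
        if missing:
            raise ValueError(
                f"{self.bait_id}-{self.prey_id}: control labels {sorted(missing)} "
                "absent from conditions"
            )

    @property
    def kinase_conditions(self) -> list[str]:
        return [c for c in self.conditions if c not in self.controls]


@dataclass
class KinaseProfileVector:
    """The set of kinase-plate spots that supported one interaction."""

    interaction_id: str
    spots: frozenset[str]

    def __post_init__(self) -> None:
        self.spots = frozenset(self.spots)


@dataclass
class CoIPMeasurement:
    """Luminescence triplicates for a pair and its background control.

    Background readings come from the same firefly-tagged protein pulled down
    with a non-related partner in the same run. ``valid`` records whether both
    proteins were expressed (measurements from unexpressed constructs are
    called ``invalid``, never positive or negative).
    """

    pair_id: str
    signal: tuple[float, float, float]
    background: tuple[float, float, float]
    valid: bool = True

    def __post_init__(self) -> None:
        self.signal = tuple(float(x) for x in self.signal)
        self.background = tuple(float(x) for x in self.background)
        self.validate()

    def validate(self) -> None:
        if len(self.signal) != 3 or len(self.background) != 3:
            raise ValueError(f"{self.pair_id}: triplicates required")
        if any(x <= 0 for x in self.signal + self.background):
            raise ValueError(f"{self.pair_id}: readings must be strictly positive")


@dataclass
class CoverageEstimate:
    """Capture-recapture estimate of interaction-space size and novelty."""

    n_literature: int
    n_screen: int
    overlap: int
    space_size_estimate: float
    novelty_fraction: float
    remaining_fraction: float
    estimator: str = "lincoln_petersen"

    def validate(self) -> None:
        if self.overlap > min(self.n_literature, self.n_screen):
            raise ValueError("overlap exceeds the smaller sample")
        if not 0.0 <= self.novelty_fraction <= 1.0:
            raise ValueError("novelty_fraction outside [0, 1]")


@dataclass
class NetworkSummary:
    """Degree/topology summary of an undirected interaction network."""

    n_nodes: int
    n_edges: int
    n_edges_outside_giant_component: int
    average_degree: float
    degree_histogram: dict[int, int]
    power_law_exponent: float | None = None

    def validate(self) -> None:
        degree_sum = sum(k * c for k, c in self.degree_histogram.items())
        if degree_sum != 2 * self.n_edges:
            raise ValueError("degree histogram does not sum to 2E")
        if self.n_nodes and not math.isclose(
            self.average_degree, 2 * self.n_edges / self.n_nodes
        ):
            raise ValueError("average_degree inconsistent with 2E/V")


@dataclass
class EnrichmentResult:
    """Observed vs expected count with an upper-tail p-value under a stated null."""

    observed: int
    expected: float
    p_value: float
    null_model: str = "binomial"

    def validate(self) -> None:
        if self.observed < 0:
            raise ValueError("observed count must be non-negative")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")


@dataclass
class SiteMatch:
    """Best consensus-motif match at one tyrosine of an interaction partner.

    ``category`` collapses match counts above 3 to the "3+" bin used when
    tabulating interactions by number of matching motif residues.
    """

    protein_id: str
    position: int
    motif_name: str
    match_count: int
    is_known_phospho_site: bool = False

    @property
    def category(self) -> str:
        return category_label(self.match_count)


def category_label(match_count: int) -> str:
    """Map a motif match count to the {0, 1, 2, 3+} category scale."""
    if match_count < 0:
        raise ValueError("match_count must be non-negative")
    return "3+" if match_count >= 3 else str(match_count)


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity over interactions, for exemplar clustering.

    ``preference`` is the self-similarity substituted on the diagonal by
    affinity propagation; by convention here it is the median of all
    off-diagonal values unless the caller overrides it.
    """

    labels: list[str]
    values: "object"  # numpy ndarray, shape (n, n)
    preference: float = field(default=float("nan"))

    def validate(self) -> None:
        import numpy as np

        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("similarity matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("similarities must lie in [0, 1]")
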