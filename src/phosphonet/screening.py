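"""Hit calling and dependence classification for pY-Y2H screen data.

The primary pooled screen is scored with the >= 2-of-N growth rule (pairs that
grew at least twice across replicas are carried into the retest). In the
pairwise retest every kinase condition and every empty-vector control is
scored in duplicate; a condition is *positive* when the duplicate rule is met
("both" duplicates by default, "any" as the permissive alternative). A pair
is then classified:

* **independent** — any empty-vector control condition is positive (growth
  without a kinase is sufficient evidence of non-conditionality, even when
  kinase conditions are also positive);
* **dependent** — no control is positive and at least one kinase condition
  is; the positive kinases form the pair's kinase profile;
* **negative** — nothing is positive.

The three labels partition the retested pairs. Baits that themselves carry a
tyrosine-kinase domain cannot strictly be called independent (their own
kinase activity may phosphorylate the partner); such calls carry a boolean
caveat flag rather than a separate class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .types import InteractionRecord, RetestMatrix, ScreenObservation

DUPLICATE_RULES = ("both", "any")


def _condition_positive(duplicates: tuple[bool, bool], duplicate_rule: str) -> bool:
    if duplicate_rule == "both":
        return duplicates[0] and duplicates[1]
    if duplicate_rule == "any":
        return duplicates[0] or duplicates[1]
    raise ValueError(f"unknown duplicate rule {duplicate_rule!r}")


def call_primary_hits(
    observations: Iterable[ScreenObservation], min_replicas: int = 2
) -> list[tuple[str, str]]:
    """Pairs whose pooled-screen growth count reaches ``min_replicas``, deduplicated.

    Order of first occurrence is preserved. Observations with fewer recorded
    replicas than ``min_replicas`` are rejected.
    """
    hits: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for obs in observations:
        if len(obs.replica_growth) < min_replicas:
            raise ValueError(
                f"{obs.bait_id}-{obs.prey_id}: {len(obs.replica_growth)} replicas "
                f"recorded, fewer than min_replicas={min_replicas}"
            )
        pair = (obs.bait_id, obs.prey_id)
        if obs.growth_count >= min_replicas and pair not in seen:
            seen.add(pair)
            hits.append(pair)
    return hits


@dataclass
class DependenceCall:
    """Outcome of classifying one retested pair."""

    bait_id: str
    prey_id: str
    label: str  # "dependent" | "independent" | "negative"
    kinase_profile: frozenset[str] = frozenset()


def call_dependence(retest: RetestMatrix, duplicate_rule: str = "both") -> DependenceCall:
    """Classify one retested pair as dependent, independent or negative."""
    positive_controls = [
        c for c in retest.controls
        if _condition_positive(retest.conditions[c], duplicate_rule)
    ]
    positive_kinases = frozenset(
        c for c in retest.kinase_conditions
        if _condition_positive(retest.conditions[c], duplicate_rule)
    )
    if positive_controls:
        label, profile = "independent", frozenset()
    elif positive_kinases:
        label, profile = "dependent", positive_kinases
    else:
        label, profile = "negative", frozenset()
    return DependenceCall(retest.bait_id, retest.prey_id, label, profile)


def check_kinase_dead(
    retest: RetestMatrix,
    dead_conditions: Sequence[str],
    duplicate_rule: str = "both",
) -> bool:
    """Phospho-consistency check against kinase-inactive constructs.

    Returns ``True`` iff none of the kinase-dead conditions is positive —
    the expected outcome for a genuinely phosphorylation-dependent pair.
    Raises on an empty dead-kinase panel (nothing to check).
    """
    if not dead_conditions:
        raise ValueError("empty kinase-dead panel: nothing to check")
    missing = set(dead_conditions) - retest.conditions.keys()
    if missing:
        raise ValueError(f"dead-kinase conditions {sorted(missing)} not in retest")
    return not any(
        _condition_positive(retest.conditions[c], duplicate_rule)
        for c in dead_conditions
    )


def classify_interactions(
    observations: Iterable[ScreenObservation],
    retests: Iterable[RetestMatrix],
    min_replicas: int = 2,
    duplicate_rule: str = "both",
    kinase_domain_baits: set[str] | frozenset[str] = frozenset(),
    source: str = "screen",
) -> list[InteractionRecord]:
    """Full calling pipeline: primary-hit rule, then retest classification.

    Only primary hits with an available retest are classified; pairs called
    ``negative`` are dropped. ``kinase_domain_baits`` marks baits whose
    independent calls carry the own-kinase-domain caveat flag.
    """
    hits = set(call_primary_hits(observations, min_replicas))
    retest_by_pair = {(r.bait_id, r.prey_id): r for r in retests}
    records: list[InteractionRecord] = []
    for pair in sorted(hits & retest_by_pair.keys()):
        call = call_dependence(retest_by_pair[pair], duplicate_rule)
        if call.label == "negative":
            continue
        records.append(
            InteractionRecord(
                call.bait_id,
                call.prey_id,
                call.label,
                call.kinase_profile,
                source,
                bait_kinase_caveat=(
                    call.label == "independent" and call.bait_id in kinase_domain_baits
                ),
            )
        )
    return records
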