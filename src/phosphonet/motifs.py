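"""Linear-motif match statistics for pY-reader interactions.

Each SH2/PTB consensus motif is a set of positional constraints around the
phospho-tyrosine anchor. A tyrosine site's *match count* is the number of
constrained offsets whose residue in the partner sequence belongs to the
allowed set; offsets falling off either sequence terminus count as
mismatches, so N-/C-terminal tyrosines remain scorable. Per interaction, the
statistic is the maximum match count over all tyrosines of the partner and
all motifs of the reader, binned on the {0, 1, 2, 3+} category scale.

The dependent-vs-independent comparison of match-count distributions uses a
two-sided Wilcoxon rank-sum test with midrank tie handling: for small groups
(up to :data:`EXACT_ENUMERATION_LIMIT` combined arrangements) the p-value is
computed by complete enumeration of group assignments; larger groups use the
tie-corrected normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .types import InteractionRecord, LinearMotif, ProteinRecord, SiteMatch

CATEGORIES = ("0", "1", "2", "3+")

#: Largest number of group assignments enumerated exactly by the rank-sum test.
EXACT_ENUMERATION_LIMIT = 20_000


def score_tyrosine_site(motif: LinearMotif, protein: ProteinRecord, position: int) -> int:
    """Count constrained offsets matched at the given tyrosine (1-based).

    Raises when the residue at ``position`` is not a tyrosine. Out-of-bounds
    offsets count as mismatches.
    """
    if not 1 <= position <= len(protein.sequence):
        raise ValueError(
            f"{protein.protein_id}: position {position} outside sequence"
        )
    if protein.sequence[position - 1] != "Y":
        raise ValueError(
            f"{protein.protein_id}: residue at {position} is "
            f"{protein.sequence[position - 1]!r}, not Y"
        )
    count = 0
    for offset, allowed in motif.constraints.items():
        p = position + offset
        if 1 <= p <= len(protein.sequence) and protein.sequence[p - 1] in allowed:
            count += 1
    return count


def best_match_for_pair(
    reader_motifs: Sequence[LinearMotif], partner: ProteinRecord
) -> SiteMatch | None:
    """Highest-scoring tyrosine over all motifs of the reader.

    Ties are broken toward the lower position, then toward the earlier motif
    in ``reader_motifs``. Returns ``None`` when the partner has no tyrosine
    (the interaction is then categorised 0 by the distribution functions).
    """
    best: SiteMatch | None = None
    for position in partner.tyrosine_positions():
        for motif in reader_motifs:
            count = score_tyrosine_site(motif, partner, position)
            if best is None or count > best.match_count:
                best = SiteMatch(
                    partner.protein_id,
                    position,
                    motif.name,
                    count,
                    is_known_phospho_site=position in partner.phospho_sites,
                )
    return best


def best_matches(
    interactions: Iterable[InteractionRecord],
    universe: Mapping[str, ProteinRecord],
    motifs: Iterable[LinearMotif],
) -> list[tuple[InteractionRecord, SiteMatch | None]]:
    """Best site match for every interaction (``None`` for tyrosine-free prey)."""
    by_reader: dict[str, list[LinearMotif]] = {}
    for m in motifs:
        by_reader.setdefault(m.reader_id, []).append(m)
    out = []
    for rec in interactions:
        reader_motifs = by_reader.get(rec.bait_id, [])
        partner = universe[rec.prey_id]
        match = best_match_for_pair(reader_motifs, partner) if reader_motifs else None
        out.append((rec, match))
    return out


def match_distribution(
    interactions: Iterable[InteractionRecord],
    universe: Mapping[str, ProteinRecord],
    motifs: Iterable[LinearMotif],
) -> dict[str, dict[str, int]]:
    """Histogram of best-match categories per dependence class.

    Returns ``{dependence: {category: count}}`` over the {0, 1, 2, 3+} bins;
    interactions whose prey has no tyrosine (or whose bait has no motif on
    file) fall in category "0". Class totals equal class sizes.
    """
    hist: dict[str, dict[str, int]] = {}
    for rec, match in best_matches(interactions, universe, motifs):
        cat = "0" if match is None else match.category
        cls = hist.setdefault(rec.dependence, {c: 0 for c in CATEGORIES})
        cls[cat] += 1
    return hist


@dataclass
class RankSumResult:
    """Two-sided Wilcoxon rank-sum comparison of two score samples."""

    statistic: float  # rank sum of the first sample, midranks
    p_value: float
    exact: bool  # True when computed by complete enumeration


def _rank_sum(values: np.ndarray, mask: np.ndarray) -> float:
    ranks = stats.rankdata(values)  # midranks
    return float(ranks[mask].sum())


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> RankSumResult:
    """Rank-sum test of ``x`` vs ``y`` with tie handling.

    When the number of distinct group assignments ``C(n_x + n_y, n_x)`` is at
    most :data:`EXACT_ENUMERATION_LIMIT`, the permutation distribution of the
    rank sum is enumerated completely; the two-sided p-value is
    ``min(1, 2 * min(P(T <= t), P(T >= t)))``. Otherwise the tie-corrected
    normal approximation (Mann-Whitney form) is used.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    obs_mask = np.zeros(n, dtype=bool)
    obs_mask[:nx] = True
    t_obs = _rank_sum(pooled, obs_mask)

    if comb(n, nx) <= EXACT_ENUMERATION_LIMIT:
        ranks = stats.rankdata(pooled)
        sums = np.array([
            ranks[list(idx)].sum() for idx in combinations(range(n), nx)
        ])
        total = sums.size
        p_le = np.count_nonzero(sums <= t_obs + 1e-9) / total
        p_ge = np.count_nonzero(sums >= t_obs - 1e-9) / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankSumResult(t_obs, p, exact=True)

    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return RankSumResult(t_obs, float(res.pvalue), exact=False)


def compare_distributions(
    dep_scores: Sequence[float], indep_scores: Sequence[float]
) -> RankSumResult:
    """Rank-sum comparison of dependent vs independent match-count samples."""
    return rank_sum_test(dep_scores, indep_scores)


def phospho_fraction_by_category(
    matches: Sequence[SiteMatch | None],
    dependence_labels: Sequence[str],
) -> dict[str, dict[str, float]]:
    """Fraction of best-match sites that are known phospho-sites.

    Returns ``{dependence: {category: fraction}}``; categories with no sites
    are reported as ``nan``. ``None`` matches (tyrosine-free prey) are
    skipped — there is no site to look up.
    """
    if len(matches) != len(dependence_labels):
        raise ValueError("matches and dependence_labels must align")
    counts: dict[str, dict[str, list[int]]] = {}
    for match, label in zip(matches, dependence_labels):
        if match is None:
            continue
        per_class = counts.setdefault(label, {c: [0, 0] for c in CATEGORIES})
        bucket = per_class[match.category]
        bucket[0] += int(match.is_known_phospho_site)
        bucket[1] += 1
    return {
        label: {
            c: (known / total if total else float("nan"))
            for c, (known, total) in per_class.items()
        }
        for label, per_class in counts.items()
    }


def predict_linear_edges(
    interactions: Iterable[InteractionRecord],
    universe: Mapping[str, ProteinRecord],
    motifs: Iterable[LinearMotif],
    min_match: int = 2,
) -> list[tuple[InteractionRecord, SiteMatch]]:
    """Edges predicted to be mediated by linear-motif recognition.

    An edge is flagged iff its best site match reaches ``min_match``
    constraints **and** that site is a known phospho-tyrosine; the predicted
    binding site is returned alongside.
    """
    flagged = []
    for rec, match in best_matches(interactions, universe, motifs):
        if (
            match is not None
            and match.match_count >= min_match
            and match.is_known_phospho_site
        ):
            flagged.append((rec, match))
    return flagged
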