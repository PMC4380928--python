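"""Network summaries, enrichment statistics and interactome coverage.

Interaction lists are treated as undirected simple graphs at the protein-pair
level: duplicate bait-prey records (the same pair supported by several
kinases, or observed in both orientations) collapse to one edge before any
topology statistic is computed.

The reader-reader enrichment asks whether edges land on pY-reader prey more
often than a random draw of prey would allow. Two null models are offered:
binomial (each edge draws its prey independently with the reader fraction of
the prey universe as success probability) and hypergeometric (edges draw
distinct prey without replacement). The null behind the originally reported
expectation is not recoverable from published information, so the model used
is always carried in the result.

Interactome coverage uses two-sample capture-recapture: with ``n1``
literature-curated interactions, ``n2`` screen interactions and ``m``
overlapping, the Lincoln-Petersen estimate of the searchable interaction
space is ``n1 * n2 / m``; the Chapman variant
``(n1 + 1)(n2 + 1) / (m + 1) - 1`` remains defined at zero overlap.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CoverageEstimate, EnrichmentResult, InteractionRecord, NetworkSummary


def interaction_graph(interactions: Iterable[InteractionRecord]) -> nx.Graph:
    """Undirected simple graph on distinct protein pairs."""
    g = nx.Graph()
    for rec in interactions:
        if rec.bait_id != rec.prey_id:
            g.add_edge(rec.bait_id, rec.prey_id)
    return g


def network_summary(interactions: Iterable[InteractionRecord]) -> NetworkSummary:
    """Topology summary: components, degrees, and the log-log degree slope.

    ``n_edges_outside_giant_component`` counts edges not inside the largest
    connected component. The power-law exponent is ``None`` whenever fewer
    than two distinct degrees are present.
    """
    g = interaction_graph(interactions)
    n_nodes, n_edges = g.number_of_nodes(), g.number_of_edges()
    if n_edges == 0:
        return NetworkSummary(n_nodes, 0, 0, 0.0, {}, None)
    giant = max(nx.connected_components(g), key=len)
    edges_in_giant = g.subgraph(giant).number_of_edges()
    degrees = [d for _, d in g.degree()]
    histogram: dict[int, int] = {}
    for d in degrees:
        histogram[d] = histogram.get(d, 0) + 1
    try:
        exponent = fit_degree_exponent(histogram)
    except ValueError:
        exponent = None
    summary = NetworkSummary(
        n_nodes,
        n_edges,
        n_edges - edges_in_giant,
        2 * n_edges / n_nodes,
        histogram,
        exponent,
    )
    summary.validate()
    return summary


def fit_degree_exponent(
    degree_histogram: Mapping[int, int], method: str = "loglog_ls"
) -> float:
    """Exponent of the degree distribution.

    ``loglog_ls`` (default): least-squares slope of log10(count) against
    log10(degree) over degrees >= 1 with positive count. ``mle``: continuous-
    approximation maximum likelihood (Clauset-style, k_min = smallest positive
    degree), returned with the same sign convention (negative).

    Raises ``ValueError`` with fewer than two distinct positive degrees.
    """
    points = sorted(
        (k, c) for k, c in degree_histogram.items() if k >= 1 and c > 0
    )
    if len(points) < 2:
        raise ValueError("need at least two distinct degrees to fit an exponent")
    ks = np.array([k for k, _ in points], dtype=float)
    cs = np.array([c for _, c in points], dtype=float)
    if method == "loglog_ls":
        slope, _ = np.polyfit(np.log10(ks), np.log10(cs), 1)
        return float(slope)
    if method == "mle":
        kmin = ks.min()
        degrees = np.repeat(ks, cs.astype(int))
        # discrete data, continuous approximation: alpha = 1 + n / sum ln(k / (kmin - 1/2))
        alpha = 1.0 + degrees.size / np.log(degrees / (kmin - 0.5)).sum()
        return float(-alpha)
    raise ValueError(f"unknown method {method!r}")


def reader_reader_enrichment(
    interactions: Iterable[InteractionRecord],
    readers: set[str] | frozenset[str],
    prey_universe: set[str] | frozenset[str],
    null_model: str = "binomial",
) -> EnrichmentResult:
    """Excess of edges whose prey is itself a pY reader.

    ``observed`` counts interaction records with reader prey; the expectation
    is ``E * p`` with ``p`` the reader fraction of the prey universe. The
    upper-tail p-value P(X >= observed) is computed under the declared null.
    """
    edges = list(interactions)
    n_edges = len(edges)
    readers_in_universe = frozenset(readers) & frozenset(prey_universe)
    observed = sum(1 for e in edges if e.prey_id in readers_in_universe)
    p = len(readers_in_universe) / len(prey_universe) if prey_universe else 0.0
    expected = n_edges * p
    if observed == 0:
        p_value = 1.0
    elif null_model == "binomial":
        p_value = float(stats.binom.sf(observed - 1, n_edges, p))
    elif null_model == "hypergeometric":
        p_value = float(
            stats.hypergeom.sf(
                observed - 1, len(prey_universe), len(readers_in_universe), n_edges
            )
        )
    else:
        raise ValueError(f"unknown null model {null_model!r}")
    result = EnrichmentResult(observed, expected, max(p_value, 0.0) or 1e-300, null_model)
    result.validate()
    return result


def ora(
    query_set: set[str] | frozenset[str],
    annotation_sets: Mapping[str, set[str]],
    universe: set[str] | frozenset[str],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set in annotation sets.

    Every set is intersected with the universe before testing; the raw
    p-value is the upper tail P(X >= overlap) of drawing ``|query|`` genes
    without replacement. Correction over the number of sets tested is
    Bonferroni (the literal "corrected for the number of tests") or ``none``.

    Returns a DataFrame indexed by set name with columns ``set_size``,
    ``overlap``, ``p_raw``, ``p_corrected``.
    """
    universe = frozenset(universe)
    query = frozenset(query_set) & universe
    rows = []
    for name, members in annotation_sets.items():
        members_in = frozenset(members) & universe
        overlap = len(query & members_in)
        if overlap == 0:
            p_raw = 1.0
        else:
            p_raw = float(
                stats.hypergeom.sf(
                    overlap - 1, len(universe), len(members_in), len(query)
                )
            )
        rows.append((name, len(members_in), overlap, min(max(p_raw, 0.0), 1.0)))
    df = pd.DataFrame(
        rows, columns=["set", "set_size", "overlap", "p_raw"]
    ).set_index("set")
    if correction == "bonferroni":
        df["p_corrected"] = multipletests(df["p_raw"], method="bonferroni")[1] if len(df) else []
    elif correction == "none":
        df["p_corrected"] = df["p_raw"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return df


def coverage_estimate(
    n_literature: int,
    n_screen: int,
    overlap: int,
    estimator: str = "lincoln_petersen",
) -> CoverageEstimate:
    """Two-sample capture-recapture estimate of the interaction space.

    ``novelty_fraction`` is the fraction of screen interactions absent from
    the literature sample (1 - overlap / n_screen); ``remaining_fraction`` is
    the estimated fraction of the space covered by neither sample.
    """
    if overlap > min(n_literature, n_screen):
        raise ValueError("overlap cannot exceed the smaller sample")
    if min(n_literature, n_screen) <= 0:
        raise ValueError("both samples must be non-empty")
    if estimator == "lincoln_petersen":
        if overlap == 0:
            raise ValueError(
                "Lincoln-Petersen is undefined at zero overlap; use estimator='chapman'"
            )
        space = n_literature * n_screen / overlap
    elif estimator == "chapman":
        space = (n_literature + 1) * (n_screen + 1) / (overlap + 1) - 1
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    novelty = 1.0 - overlap / n_screen
    discovered = n_literature + n_screen - overlap
    remaining = 1.0 - discovered / space
    est = CoverageEstimate(
        n_literature, n_screen, overlap, space, novelty, remaining, estimator
    )
    est.validate()
    return est
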