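"""Motif scoring, per-pair best matches and the rank-sum comparison."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphonet.motifs import (
    best_match_for_pair,
    match_distribution,
    phospho_fraction_by_category,
    predict_linear_edges,
    rank_sum_test,
    score_tyrosine_site,
)
from phosphonet.types import InteractionRecord, LinearMotif, ProteinRecord, SiteMatch


def protein(seq, **kw):
    return ProteinRecord(kw.pop("protein_id", "P1"), seq, **kw)


class TestScoreTyrosineSite:
    def test_full_match_counts_all_constraints(self, pik3r3_motif):
        assert score_tyrosine_site(pik3r3_motif, protein("AYEAM"), 2) == 2

    def test_no_match(self, pik3r3_motif):
        assert score_tyrosine_site(pik3r3_motif, protein("AYAAA"), 2) == 0

    def test_out_of_bounds_offset_is_a_mismatch(self):
        motif = LinearMotif("R", "m", {-3: {"N"}})
        assert score_tyrosine_site(motif, protein("AYAAA"), 2) == 0

    def test_non_tyrosine_position_is_an_error(self, pik3r3_motif):
        with pytest.raises(ValueError, match="not Y"):
            score_tyrosine_site(pik3r3_motif, protein("AYEAM"), 1)

    def test_agrees_with_window_oracle_on_random_triples(self, rng):
        """Scoring equals a padded-window comparison oracle."""
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(500):
            seq = "".join(rng.choice(alphabet, size=rng.integers(11, 40)))
            pos = int(rng.integers(1, len(seq) + 1))
            seq = seq[: pos - 1] + "Y" + seq[pos:]
            offsets = rng.choice([o for o in range(-5, 6) if o], size=rng.integers(1, 4),
                                 replace=False)
            motif = LinearMotif("R", "m", {
                int(o): frozenset(rng.choice(alphabet, size=rng.integers(1, 3)))
                for o in offsets
            })
            window = "-" * 5 + seq + "-" * 5  # pad so every offset indexes safely
            expected = sum(
                window[pos - 1 + 5 + o] in allowed
                for o, allowed in motif.constraints.items()
            )
            assert score_tyrosine_site(motif, protein(seq), pos) == expected


class TestBestMatch:
    def test_no_tyrosine_gives_none(self, pik3r3_motif):
        assert best_match_for_pair([pik3r3_motif], protein("MAKA")) is None

    def test_returns_highest_scoring_site(self, pik3r3_motif):
        # Y2 scores 0, Y6 scores 2
        match = best_match_for_pair([pik3r3_motif], protein("AYAAAYEAM"))
        assert (match.position, match.match_count, match.category) == (6, 2, "2")

    def test_tie_breaks_to_lower_position_then_motif_order(self):
        m1 = LinearMotif("R", "m1", {+1: {"E"}})
        m2 = LinearMotif("R", "m2", {+1: {"E"}})
        match = best_match_for_pair([m1, m2], protein("YEAYEA"))
        assert (match.position, match.motif_name) == (1, "m1")

    def test_exhaustive_scan_oracle(self, rng):
        """Best match equals the max over an explicit Y x motif scan."""
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        motifs = [
            LinearMotif("R", f"m{i}", {
                int(o): frozenset(rng.choice(alphabet, size=2))
                for o in rng.choice([-2, -1, 1, 2, 3], size=2, replace=False)
            })
            for i in range(3)
        ]
        for _ in range(100):
            seq = "".join(rng.choice(alphabet, size=60))
            p = protein(seq)
            got = best_match_for_pair(motifs, p)
            scores = [
                score_tyrosine_site(m, p, pos)
                for pos in p.tyrosine_positions() for m in motifs
            ]
            if not scores:
                assert got is None
            else:
                assert got.match_count == max(scores)

    def test_pik3r3_plekhs1_like_site(self, pik3r3_motif):
        """A pYExM match at Y68 of a PLEKHS1-like sequence is the best site."""
        seq = ["A"] * 80
        seq[67] = "Y"; seq[68] = "E"; seq[70] = "M"  # Y68, E69, M71 (1-based)
        seq[28] = "Y"; seq[73] = "Y"  # other tyrosines, no motif context
        match = best_match_for_pair([pik3r3_motif], protein("".join(seq)))
        assert (match.position, match.match_count) == (68, 2)


class TestMatchDistribution:
    def test_totals_equal_class_sizes(self, default_study):
        net = default_study["network"]
        universe = {p.protein_id: p for p in default_study["proteins"]}
        hist = match_distribution(net.interactions, universe, default_study["motifs"])
        for label in hist:
            n_class = sum(e.dependence == label for e in net.interactions)
            assert sum(hist[label].values()) == n_class

    def test_empty_interactions_give_empty_histogram(self):
        assert match_distribution([], {}, []) == {}

    def test_identical_sets_give_identical_histograms(self, pik3r3_motif):
        universe = {"R": protein("Y" + "A" * 9, protein_id="R", is_reader=True,
                                 reader_domains={"SH2"}),
                    "P": protein("AYEAM", protein_id="P")}
        edges = [InteractionRecord("R", "P", "dependent", {"FYN"}),
                 InteractionRecord("R", "P", "independent")]
        motif = LinearMotif("R", "m", pik3r3_motif.constraints)
        hist = match_distribution(edges, universe, [motif])
        assert hist["dependent"] == hist["independent"]


def midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        for k in range(i, j + 1):
            ranks[order[k]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def enumeration_oracle(x, y, alternative):
    """Independent exhaustive enumeration of rank-sum splits."""
    pooled = list(x) + list(y)
    ranks = midranks(pooled)
    n, nx = len(pooled), len(x)
    t_obs = sum(ranks[:nx])
    sums = [sum(ranks[i] for i in idx) for idx in combinations(range(n), nx)]
    p_ge = sum(s >= t_obs - 1e-9 for s in sums) / len(sums)
    p_le = sum(s <= t_obs + 1e-9 for s in sums) / len(sums)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)

    def test_separated_samples_one_sided_exact(self):
        # full enumeration of C(6,3) = 20 splits: one split as extreme
        res = rank_sum_test([5, 6, 7], [1, 2, 3], alternative="greater")
        assert res.exact and res.p_value == pytest.approx(1 / 20)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.integers(0, 4), min_size=2, max_size=8),
        y=st.lists(st.integers(0, 4), min_size=2, max_size=8),
        alternative=st.sampled_from(["two-sided", "greater", "less"]),
    )
    def test_exact_p_matches_enumeration_oracle_with_ties(self, x, y, alternative):
        res = rank_sum_test(x, y, alternative)
        assert res.exact
        assert res.p_value == pytest.approx(enumeration_oracle(x, y, alternative))


class TestPhosphoFractions:
    def test_exact_fractions_per_category_and_class(self):
        matches = [
            SiteMatch("P1", 3, "m", 2, is_known_phospho_site=True),
            SiteMatch("P2", 5, "m", 2, is_known_phospho_site=False),
            SiteMatch("P3", 8, "m", 0, is_known_phospho_site=False),
            SiteMatch("P4", 2, "m", 4, is_known_phospho_site=True),
        ]
        labels = ["dependent", "dependent", "dependent", "independent"]
        frac = phospho_fraction_by_category(matches, labels)
        assert frac["dependent"]["2"] == pytest.approx(0.5)
        assert frac["dependent"]["0"] == pytest.approx(0.0)
        assert frac["independent"]["3+"] == pytest.approx(1.0)
        assert np.isnan(frac["dependent"]["1"])

    def test_all_sites_known_when_rate_is_one(self):
        from phosphonet.motifs import best_matches
        from phosphonet.simulate import SimulationConfig, generate_truth_network, generate_universe

        cfg = SimulationConfig(seed=13, n_genes=60, n_readers=6, n_true_edges=30,
                               phospho_site_rate=1.0)
        universe = generate_universe(cfg)
        net = generate_truth_network(cfg, universe)
        proteins = {p.protein_id: p for p in universe[0]}
        pairs = best_matches(net.interactions, proteins, universe[1])
        matches = [m for _, m in pairs if m is not None]
        frac = phospho_fraction_by_category(
            matches, ["dependent"] * len(matches)
        )
        for value in frac["dependent"].values():
            assert np.isnan(value) or value == 1.0


class TestPredictLinearEdges:
    def test_conjunction_rule(self, pik3r3_motif):
        universe = {
            "P_site": protein("AYEAM", protein_id="P_site", phospho_sites={2}),
            "P_nosite": protein("AYEAM", protein_id="P_nosite"),
            "P_weak": protein("AYEAA", protein_id="P_weak", phospho_sites={2}),
        }
        motif = LinearMotif("R", "m", pik3r3_motif.constraints)
        edges = [InteractionRecord("R", pid, "dependent", {"FYN"}) for pid in universe]
        flagged = predict_linear_edges(edges, universe, [motif], min_match=2)
        assert [(rec.prey_id, m.position) for rec, m in flagged] == [("P_site", 2)]

    def test_boundary_min_match_flags(self, pik3r3_motif):
        universe = {"P": protein("AYEAA", protein_id="P", phospho_sites={2})}
        motif = LinearMotif("R", "m", pik3r3_motif.constraints)
        edges = [InteractionRecord("R", "P", "dependent", {"FYN"})]
        assert predict_linear_edges(edges, universe, [motif], min_match=1)
        assert not predict_linear_edges(edges, universe, [motif], min_match=2)

    def test_recovers_exactly_the_planted_edges(self):
        from phosphonet.simulate import SimulationConfig, generate_truth_network, generate_universe

        cfg = SimulationConfig(seed=14, n_genes=120, n_readers=12, n_true_edges=60,
                               frac_dependent=1.0, motif_plant_rate=0.7,
                               phospho_site_rate=0.0)
        universe = generate_universe(cfg)
        net = generate_truth_network(cfg, universe)
        proteins = {p.protein_id: p for p in universe[0]}
        flagged = predict_linear_edges(
            net.interactions, proteins, universe[1],
            min_match=cfg.motif_n_constraints,
        )
        # with no background phospho-sites, flagged edges = planted edges
        assert {rec.pair for rec, _ in flagged} == set(net.planted_sites)
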