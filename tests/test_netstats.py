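"""Network summaries, enrichment tails, ORA and capture-recapture coverage."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphonet.netstats import (
    coverage_estimate,
    fit_degree_exponent,
    network_summary,
    ora,
    reader_reader_enrichment,
)
from phosphonet.types import InteractionRecord


def edge(bait, prey, dependence="dependent"):
    profile = {"FYN"} if dependence == "dependent" else set()
    return InteractionRecord(bait, prey, dependence, profile)


class TestNetworkSummary:
    def test_triangle_plus_disjoint_edge(self):
        edges = [edge("A", "B"), edge("B", "C"), edge("C", "A"), edge("D", "E")]
        s = network_summary(edges)
        assert (s.n_nodes, s.n_edges) == (5, 4)
        assert s.n_edges_outside_giant_component == 1
        assert s.average_degree == pytest.approx(2 * 4 / 5)

    def test_empty_edge_list(self):
        s = network_summary([])
        assert (s.n_nodes, s.n_edges, s.n_edges_outside_giant_component) == (0, 0, 0)
        assert s.power_law_exponent is None

    def test_duplicate_and_reversed_records_collapse(self):
        edges = [edge("A", "B"), edge("A", "B", "independent"), edge("B", "A")]
        assert network_summary(edges).n_edges == 1

    def test_degree_histogram_sums_to_twice_edges(self, default_study):
        s = network_summary(default_study["network"].interactions)
        assert sum(k * c for k, c in s.degree_histogram.items()) == 2 * s.n_edges
        s.validate()


class TestDegreeExponent:
    def test_recovers_generating_exponent(self):
        hist = {k: 1000 * k**-2 for k in range(1, 11)}  # exact k^-2 counts
        assert fit_degree_exponent(hist) == pytest.approx(-2.0, abs=1e-6)

    def test_single_degree_is_undefined(self):
        with pytest.raises(ValueError, match="two distinct degrees"):
            fit_degree_exponent({3: 17})

    def test_matches_closed_form_least_squares(self):
        hist = {1: 8, 2: 3, 4: 1}
        xs = [math.log10(k) for k in hist]
        ys = [math.log10(c) for c in hist.values()]
        xbar, ybar = sum(xs) / 3, sum(ys) / 3
        slope = sum((x - xbar) * (y - ybar) for x, y in zip(xs, ys)) / sum(
            (x - xbar) ** 2 for x in xs
        )
        assert fit_degree_exponent(hist) == pytest.approx(slope)

    def test_mle_recovers_steep_exponent_sign_convention(self):
        hist = {k: round(10000 * k**-3.0) for k in range(1, 30)}
        got = fit_degree_exponent(hist, method="mle")
        assert got < -2.0  # negative, steeper than the shallow regime


def binomial_tail_oracle(k, n, p):
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


class TestReaderReaderEnrichment:
    def test_no_readers_gives_p_one(self):
        res = reader_reader_enrichment([edge("A", "B")], set(), {"B", "C"})
        assert (res.observed, res.expected, res.p_value) == (0, 0.0, 1.0)

    def test_binomial_tail_matches_direct_summation(self):
        edges = [edge("R", f"P{i}") for i in range(5)] + [
            edge("R", f"Q{i}") for i in range(5)
        ]
        readers = {f"P{i}" for i in range(5)} | {"R"}
        universe = {f"P{i}" for i in range(5)} | {f"X{i}" for i in range(45)}
        res = reader_reader_enrichment(edges, readers, universe)
        p = 5 / 50
        assert res.expected == pytest.approx(10 * p)
        assert res.p_value == pytest.approx(binomial_tail_oracle(res.observed, 10, p), abs=1e-4)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 25),
        obs=st.integers(0, 25),
        p100=st.integers(1, 99),
    )
    def test_tails_agree_with_exhaustive_pmf_summation(self, n, obs, p100):
        from scipy import stats

        obs = min(obs, n)
        p = p100 / 100
        tail = float(stats.binom.sf(obs - 1, n, p)) if obs else 1.0
        assert tail == pytest.approx(binomial_tail_oracle(obs, n, p), rel=1e-9)

    def test_hypergeometric_null_available(self):
        edges = [edge("R", "P0"), edge("R", "P1")]
        res = reader_reader_enrichment(
            edges, {"P0", "P1"}, {f"P{i}" for i in range(10)},
            null_model="hypergeometric",
        )
        # P(X >= 2) drawing 2 from 10 with 2 readers = 1/C(10,2)
        assert res.p_value == pytest.approx(1 / math.comb(10, 2))


class TestORA:
    def test_query_identical_to_set_hits_point_mass(self):
        universe = {f"g{i}" for i in range(50)}
        query = {f"g{i}" for i in range(5)}
        df = ora(query, {"hit": set(query)}, universe)
        assert df.loc["hit", "overlap"] == 5
        assert df.loc["hit", "p_raw"] == pytest.approx(1 / math.comb(50, 5))

    def test_disjoint_set_gives_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        df = ora({"g0", "g1"}, {"other": {"g10", "g11"}}, universe)
        assert df.loc["other", "p_raw"] == 1.0

    def test_single_set_correction_is_identity(self):
        universe = {f"g{i}" for i in range(20)}
        df = ora({"g0", "g1"}, {"s": {"g0", "g5"}}, universe)
        assert df.loc["s", "p_corrected"] == pytest.approx(df.loc["s", "p_raw"])

    def test_bonferroni_multiplies_by_set_count(self):
        universe = {f"g{i}" for i in range(30)}
        sets = {f"s{j}": {f"g{j}", f"g{j + 1}"} for j in range(4)}
        df = ora({"g0", "g1", "g2"}, sets, universe)
        for name in sets:
            expected = min(1.0, df.loc[name, "p_raw"] * 4)
            assert df.loc[name, "p_corrected"] == pytest.approx(expected)


class TestCoverage:
    def test_literature_comparison_closed_form(self):
        est = coverage_estimate(147, 79, 15)
        assert est.space_size_estimate == pytest.approx(147 * 79 / 15)
        assert est.novelty_fraction == pytest.approx(0.810, abs=5e-4)
        assert est.remaining_fraction == pytest.approx(0.727, abs=5e-4)

    def test_complete_overlap_leaves_nothing(self):
        est = coverage_estimate(10, 10, 10)
        assert est.space_size_estimate == 10
        assert est.novelty_fraction == 0.0
        assert est.remaining_fraction == pytest.approx(0.0)

    def test_remaining_decreases_with_overlap(self):
        values = [coverage_estimate(100, 80, m).remaining_fraction for m in range(5, 40, 5)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_zero_overlap_requires_chapman(self):
        with pytest.raises(ValueError, match="chapman"):
            coverage_estimate(10, 10, 0)
        est = coverage_estimate(10, 10, 0, estimator="chapman")
        assert est.space_size_estimate == pytest.approx(11 * 11 / 1 - 1)

    def test_overlap_cannot_exceed_samples(self):
        with pytest.raises(ValueError, match="overlap"):
            coverage_estimate(5, 10, 7)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        n1=st.integers(1, 500), n2=st.integers(1, 500),
        data=st.data(),
    )
    def test_novelty_always_a_fraction(self, n1, n2, data):
        m = data.draw(st.integers(1, min(n1, n2)))
        est = coverage_estimate(n1, n2, m)
        assert 0.0 <= est.novelty_fraction <= 1.0
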