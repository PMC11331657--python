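"""Shared-event matching, concordance statistics, Venn regions, gene ranking."""

import numpy as np
import pytest

from spliceconcord.errors import DuplicateKeyError
from spliceconcord.events import event_key
from spliceconcord.shared import (
    MatchedEventPair,
    classify_concordance,
    collapse_duplicate_keys,
    concordance_summary,
    delta_psi_correlation,
    filter_events,
    match_shared_events,
    top_genes_by_event_count,
    venn_counts,
)

from conftest import make_event


def _pair(delta_a, delta_b, gene="g1", symbol=None, shift=0):
    a = make_event(
        "SE", gene_id=gene, gene_symbol=symbol or gene.upper(), delta_psi=delta_a,
        coords={"upstream": (50 + shift, 80 + shift), "target": (100 + shift, 200 + shift),
                "downstream": (250 + shift, 300 + shift)},
    )
    b = make_event(
        "SE", gene_id=gene, gene_symbol=symbol or gene.upper(), delta_psi=delta_b,
        coords=dict(a.coords), contrast_label="kd2",
    )
    return MatchedEventPair(event_key(a), a, b, classify_concordance(delta_a, delta_b))


class TestFilterEvents:
    def test_strict_inequality_at_threshold(self):
        events = [make_event(fdr=f, event_id=str(i)) for i, f in enumerate([0.01, 0.05, 0.2])]
        kept = filter_events(events, 0.05)
        assert [e.fdr for e in kept] == [0.01]

    def test_threshold_one_keeps_everything(self):
        events = [make_event(fdr=f) for f in (0.0, 0.5, 0.999)]
        assert filter_events(events, 1.0) == events

    def test_empty_input(self):
        assert filter_events([], 0.05) == []

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_threshold_outside_range_rejected(self, bad):
        with pytest.raises(ValueError):
            filter_events([], bad)


class TestConcordance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(0.3, 0.1, True), (0.3, -0.1, False), (0.0, 0.2, False), (-0.2, -0.4, True)],
    )
    def test_sign_product_rule(self, a, b, expected):
        assert classify_concordance(a, b) is expected

    def test_missing_delta_rejected(self):
        with pytest.raises(ValueError):
            classify_concordance(None, 0.1)


class TestMatching:
    def test_intersection_of_keys(self):
        a_events = [_pair(0.1, 0.1, shift=s).event_a for s in (0, 1000, 2000)]
        b_events = [_pair(0.1, 0.1, shift=s).event_b for s in (1000, 2000, 3000)]
        pairs = match_shared_events(a_events, b_events)
        assert len(pairs) == 2
        # brute-force double loop over all key pairs agrees
        brute = sum(
            1 for x in a_events for y in b_events if event_key(x) == event_key(y)
        )
        assert brute == 2

    def test_self_match_pairs_every_event_concordantly(self):
        events = [_pair(0.2, 0.2, shift=s).event_a for s in (0, 500)]
        pairs = match_shared_events(events, events)
        assert len(pairs) == len(events)
        assert all(p.concordant for p in pairs)

    def test_empty_b_gives_no_pairs(self):
        assert match_shared_events([make_event()], []) == []

    def test_duplicate_key_within_one_list_rejected(self):
        ev = make_event()
        with pytest.raises(DuplicateKeyError):
            match_shared_events([ev, make_event(event_id="2")], [])

    def test_collapse_keeps_smallest_fdr_then_pvalue(self):
        worst = make_event(event_id="a", fdr=0.04, pvalue=0.01)
        best = make_event(event_id="b", fdr=0.01, pvalue=0.005)
        tied = make_event(event_id="c", fdr=0.01, pvalue=0.001)
        collapsed = collapse_duplicate_keys([worst, best, tied])
        assert [e.event_id for e in collapsed] == ["c"]

    def test_pairs_sorted_by_type_contig_coordinate(self, small_fixture):
        _, _, _, tables, _ = small_fixture
        a = [e for t in tables["kd1"].values() for e in t]
        b = [e for t in tables["kd2"].values() for e in t]
        pairs = match_shared_events(collapse_duplicate_keys(a), collapse_duplicate_keys(b))
        keys = [
            (p.key.event_type, p.key.contig, min(s for s, _ in p.event_a.coords.values()))
            for p in pairs
        ]
        assert keys == sorted(keys)

    def test_swapping_contrasts_preserves_statistics(self, small_fixture):
        _, _, _, tables, _ = small_fixture
        a = collapse_duplicate_keys([e for t in tables["kd1"].values() for e in t])
        b = collapse_duplicate_keys([e for t in tables["kd2"].values() for e in t])
        s_ab = concordance_summary(match_shared_events(a, b))
        s_ba = concordance_summary(match_shared_events(b, a))
        assert s_ab.n_shared_events == s_ba.n_shared_events
        assert s_ab.n_concordant == s_ba.n_concordant
        assert s_ab.pearson_r == pytest.approx(s_ba.pearson_r)


class TestSummary:
    def test_fraction_and_percentage(self):
        pairs = [_pair(0.1, 0.1, shift=i * 1000) for i in range(4)]
        pairs += [_pair(0.1, -0.1, shift=(i + 4) * 1000) for i in range(4)]
        s = concordance_summary(pairs)
        assert s.n_shared_events == 8 and s.n_concordant == 4
        assert s.concordance_fraction == pytest.approx(0.5)
        assert s.concordance_percent == 50.0

    def test_all_or_none_concordant(self):
        all_conc = [_pair(0.1, 0.2, shift=i * 1000) for i in range(3)]
        none_conc = [_pair(0.1, -0.2, shift=i * 1000) for i in range(3)]
        assert concordance_summary(all_conc).concordance_fraction == 1.0
        assert concordance_summary(none_conc).concordance_fraction == 0.0

    def test_empty_input_has_undefined_fraction(self):
        s = concordance_summary([])
        assert s.n_shared_events == 0
        assert s.concordance_fraction is None and s.concordance_percent is None

    def test_gene_and_type_tallies(self):
        pairs = [
            _pair(0.1, 0.1, gene="g1", shift=0),
            _pair(0.1, 0.1, gene="g1", shift=1000),
            _pair(0.1, 0.1, gene="g2", shift=2000),
        ]
        s = concordance_summary(pairs)
        assert s.n_genes == 2
        assert s.per_type_counts == {"SE": 3}


class TestDeltaPsiCorrelation:
    def test_perfect_linear_relationships(self):
        pos = [_pair(d, 2 * d, shift=i * 1000) for i, d in enumerate([0.1, 0.2, 0.3, -0.1])]
        neg = [_pair(d, -d, shift=i * 1000) for i, d in enumerate([0.1, 0.2, 0.3, -0.1])]
        assert delta_psi_correlation(pos)[0] == pytest.approx(1.0)
        assert delta_psi_correlation(neg)[0] == pytest.approx(-1.0)

    def test_against_textbook_formula_oracle(self):
        data = [(0.1, 0.2), (0.2, 0.1), (0.3, 0.4), (-0.1, -0.2), (-0.4, -0.3)]
        pairs = [_pair(a, b, shift=i * 1000) for i, (a, b) in enumerate(data)]
        xs = np.array([a for a, _ in data])
        ys = np.array([b for _, b in data])
        # direct covariance / variance arithmetic, independent of scipy
        expected = (
            ((xs - xs.mean()) * (ys - ys.mean())).sum()
            / np.sqrt(((xs - xs.mean()) ** 2).sum() * ((ys - ys.mean()) ** 2).sum())
        )
        r, p = delta_psi_correlation(pairs)
        assert r == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= p <= 1.0

    def test_constant_vector_rejected(self):
        pairs = [_pair(0.1, b, shift=i * 1000) for i, b in enumerate([0.1, 0.2, 0.3])]
        with pytest.raises(ValueError, match="constant"):
            delta_psi_correlation(pairs)

    def test_too_few_pairs_rejected(self):
        pairs = [_pair(0.1, 0.2, shift=0), _pair(0.2, 0.1, shift=1000)]
        with pytest.raises(ValueError):
            delta_psi_correlation(pairs)


class TestVennCounts:
    def test_three_set_region_enumeration(self):
        regions = venn_counts({"A": {"a", "b"}, "B": {"b", "c"}, "C": {"b"}})
        assert regions[frozenset("ABC")] == 1  # b
        assert regions[frozenset("AB")] == 0
        assert regions[frozenset("A")] == 1  # a
        assert regions[frozenset("B")] == 1  # c
        assert regions[frozenset("C")] == 0
        assert len(regions) == 7

    def test_disjoint_and_identical_sets(self):
        disjoint = venn_counts({"A": {1, 2}, "B": {3}})
        assert disjoint[frozenset("AB")] == 0
        identical = venn_counts({"A": {1, 2}, "B": {1, 2}})
        assert identical[frozenset("AB")] == 2
        assert identical[frozenset("A")] == identical[frozenset("B")] == 0

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            venn_counts({"A": {1}})


class TestTopGenes:
    def test_ranked_by_count_then_symbol(self):
        pairs = (
            [_pair(0.1, 0.1, gene="g1", symbol="Zeta", shift=i * 1000) for i in range(3)]
            + [_pair(0.1, 0.1, gene="g2", symbol="Alpha", shift=(3) * 1000)]
        )
        assert top_genes_by_event_count(pairs, 10) == [("Zeta", 3), ("Alpha", 1)]

    def test_tie_breaks_lexicographically_and_truncates(self):
        pairs = [
            _pair(0.1, 0.1, gene="g1", symbol="b", shift=0),
            _pair(0.1, 0.1, gene="g1", symbol="b", shift=1000),
            _pair(0.1, 0.1, gene="g2", symbol="a", shift=2000),
            _pair(0.1, 0.1, gene="g2", symbol="a", shift=3000),
            _pair(0.1, 0.1, gene="g3", symbol="c", shift=4000),
        ]
        assert top_genes_by_event_count(pairs, 2) == [("a", 2), ("b", 2)]

    def test_empty_pairs(self):
        assert top_genes_by_event_count([], 5) == []

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            top_genes_by_event_count([], 0)
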