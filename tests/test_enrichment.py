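"""GO enrichment: term levels, the hypergeometric tail, BY adjustment, the
network-level enrichment procedure and the cancer-keyword classifier."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from mirpin.enrichment import (
    KeywordRule,
    adjust_benjamini_yekutieli,
    classify_cancer_related,
    compute_term_levels,
    enrich_pin,
    hypergeometric_upper_tail,
)
from mirpin.io import AnnotationSet, Ontology, TermRecord, UsageError
from mirpin.network import PIN
from mirpin.simulate import simulate_ontology


def _ontology(edges, names=None, namespace=None):
    parents = {}
    nodes = set()
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
        nodes |= {child, parent}
    return Ontology({
        n: TermRecord(n, (names or {}).get(n, n), namespace,
                      tuple(sorted(parents.get(n, ()))))
        for n in nodes
    })


class TestTermLevels:
    def test_root_and_child(self):
        onto = _ontology([("a", "root")])
        levels = compute_term_levels(onto)
        assert levels == {"root": 0, "a": 1}

    def test_diamond_takes_shortest_path(self):
        onto = _ontology([("a", "root"), ("b", "root"), ("c", "a"), ("c", "b")])
        assert compute_term_levels(onto)["c"] == 2

    def test_longer_alternative_path_ignored(self):
        onto = _ontology([("a", "root"), ("b", "root"), ("c", "a"), ("c", "b"),
                          ("d", "a"), ("c", "d")])
        assert compute_term_levels(onto)["c"] == 2

    def test_level_invariants_hold_on_random_dags(self, rng):
        onto, _, _ = simulate_ontology(5, 3, 50, 3, 0, seed=17)
        levels = compute_term_levels(onto)
        for term in onto.terms.values():
            if term.parents:
                assert levels[term.term_id] >= 1
                assert levels[term.term_id] <= min(levels[p] for p in term.parents) + 1


class TestHypergeometricTail:
    def test_worked_example(self):
        # k=3 of n=5 draws in a K=4 category of N=10: 66/252
        assert hypergeometric_upper_tail(3, 4, 5, 10) == pytest.approx(66 / 252)

    def test_degenerate_cases(self):
        assert hypergeometric_upper_tail(0, 4, 5, 10) == 1.0
        assert hypergeometric_upper_tail(5, 5, 5, 5) == 1.0

    def test_matches_exhaustive_enumeration_for_small_universes(self):
        """Compare against direct counting of all C(N, n) draws for every
        parameter combination with N <= 12."""
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    category = set(range(K))
                    total = comb(N, n)
                    tail_counts = np.zeros(n + 2)
                    for draw in itertools.combinations(range(N), n):
                        k = len(category.intersection(draw))
                        tail_counts[k] += 1
                    for k in range(0, min(K, n) + 1):
                        expected = tail_counts[k:].sum() / total
                        got = hypergeometric_upper_tail(k, K, n, N)
                        assert got == pytest.approx(expected, abs=1e-12), (k, K, n, N)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(UsageError):
            hypergeometric_upper_tail(5, 4, 3, 10)


def _by_oracle(p):
    """Step-down hand formula: adj_i = min over j with p_j >= p_i of
    m*c(m)*p_j/rank_j, capped at 1."""
    m = len(p)
    c = sum(1.0 / i for i in range(1, m + 1))
    order = np.argsort(p)
    adj_sorted = [m * c * p[order[i]] / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        adj_sorted[i] = min(adj_sorted[i], adj_sorted[i + 1])
    out = np.empty(m)
    for i in range(m):
        out[order[i]] = min(adj_sorted[i], 1.0)
    return out


class TestBenjaminiYekutieli:
    def test_single_p_unchanged(self):
        assert adjust_benjamini_yekutieli([0.03]) == pytest.approx([0.03])

    def test_worked_three_value_case(self):
        # c(3) = 11/6; 3 * (11/6) * 0.01 / 1 = 0.055, monotonized across ranks
        got = adjust_benjamini_yekutieli([0.01, 0.02, 0.03])
        assert got == pytest.approx([0.055, 0.055, 0.055])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_step_down_oracle_and_dominates_bh(self, p):
        got = adjust_benjamini_yekutieli(p)
        assert np.allclose(got, _by_oracle(p), atol=1e-12)
        bh = multipletests(p, method="fdr_bh")[1]
        assert (got >= bh - 1e-12).all()
        assert (got >= np.asarray(p) - 1e-12).all()

    def test_order_preserving_and_idempotent_on_ties(self):
        p = [0.5, 0.01, 0.01, 0.2]
        adj = adjust_benjamini_yekutieli(p)
        assert adj[1] == adj[2]
        assert np.argsort(adj, kind="stable").tolist() == np.argsort(p, kind="stable").tolist()

    def test_out_of_range_rejected(self):
        with pytest.raises(UsageError):
            adjust_benjamini_yekutieli([0.5, 1.5])


class TestKeywordClassifier:
    @pytest.mark.parametrize("name, expected", [
        ("Negative regulation of programmed cell death", True),
        ("Microtubule cytoskeleton", True),
        ("Epidermal growth factor receptor signaling pathway", True),
        ("Actin filament capping", True),
        ("nucleotide binding", False),
    ])
    def test_default_rule(self, name, expected):
        assert classify_cancer_related(name) is expected

    def test_restricted_rule(self):
        rule = KeywordRule(("apoptosis", "cell death", "cell proliferation"))
        assert classify_cancer_related("Induction of apoptosis", rule)
        assert not classify_cancer_related("BMP signaling pathway", rule)

    def test_rules_must_be_lowercase_and_non_empty(self):
        with pytest.raises(UsageError):
            KeywordRule(())
        with pytest.raises(UsageError):
            KeywordRule(("Apoptosis",))


def _planted_setup(seed, pin_size=20, overlap=15):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(300)]
    pin_genes = list(rng.choice(genes, size=pin_size, replace=False))
    onto, ann, truth = simulate_ontology(
        6, 2, 300, planted_term_level=5, planted_overlap=overlap, seed=seed,
        genes=genes, pin_genes=pin_genes, planted_term_size=30)
    pin = PIN("mir-hub", frozenset(pin_genes[:5]), frozenset(pin_genes[5:]),
              frozenset())
    return pin, ann, onto, truth


class TestEnrichPin:
    def test_small_networks_are_skipped(self):
        pin, ann, onto, _ = _planted_setup(1)
        tiny = PIN("m", frozenset(list(pin.l0)[:3]), frozenset(list(pin.l1)[:2]),
                   frozenset())
        assert enrich_pin(tiny, ann, onto, min_pin_size=6) == []

    def test_planted_term_is_top_hit_across_seeds(self):
        wins = 0
        for seed in range(10):
            pin, ann, onto, truth = _planted_setup(seed)
            results = enrich_pin(pin, ann, onto, min_pin_size=6, min_level=5,
                                 alpha=1e-4)
            if results and results[0].term_id == truth.planted_term:
                wins += 1
        assert wins >= 9

    def test_member_genes_equal_set_intersection(self):
        pin, ann, onto, _ = _planted_setup(3)
        for res in enrich_pin(pin, ann, onto, keep_all=True):
            assert res.member_genes == pin.nodes & ann.mapping[res.term_id]
            assert res.k == len(res.member_genes)
            assert 0 <= res.k <= min(res.K, res.n)
            assert res.p_adj >= res.p - 1e-12

    def test_level_filter_excludes_shallow_terms(self):
        pin, ann, onto, _ = _planted_setup(4)
        levels = compute_term_levels(onto)
        for res in enrich_pin(pin, ann, onto, min_level=5, keep_all=True):
            assert levels[res.term_id] >= 5

    def test_empty_universe_rejected(self):
        pin, _, onto, _ = _planted_setup(5)
        with pytest.raises(UsageError):
            enrich_pin(pin, AnnotationSet({}), onto)

    def test_null_false_hit_rate_controlled(self):
        """Under uniform random annotation and a random network, the fraction
        of networks with any BY-adjusted hit at alpha=0.05 stays within the
        nominal level plus 3 binomial SEs (200 null networks)."""
        onto, ann, _ = simulate_ontology(6, 2, 300, 5, 0, seed=99)
        genes = sorted(ann.universe)
        rng = np.random.default_rng(12345)
        false_hits = 0
        n_pins = 200
        for _ in range(n_pins):
            pick = rng.choice(len(genes), size=20, replace=False)
            pin = PIN("null", frozenset(genes[i] for i in pick), frozenset(),
                      frozenset())
            results = enrich_pin(pin, ann, onto, min_pin_size=6, min_level=5,
                                 alpha=0.05)
            false_hits += bool(results)
        se = np.sqrt(0.05 * 0.95 / n_pins)
        assert false_hits / n_pins <= 0.05 + 3 * se
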