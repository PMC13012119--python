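"""Hypergeometric tail, BH step-up and term enrichment, each checked against
an independent route (full enumeration, scipy/statsmodels, per-term loop)."""

import math

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from regdiscover.ontology_enrich import (TermAnnotation, bh_adjust, enrich_terms,
                                         hypergeom_upper_tail, read_gmt, top_terms)


def enumerate_upper_tail(k, K, n, N):
    """Exact tail by summing the pmf over the full support with math.comb."""
    total = math.comb(N, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i)
               for i in range(k, min(K, n) + 1)) / total


def test_certain_event():
    assert hypergeom_upper_tail(0, 5, 5, 10) == 1.0


def test_exact_combinatorial_value():
    # all 5 query genes inside a 5-gene term in a 10-gene universe
    assert hypergeom_upper_tail(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)


def test_matches_enumeration_on_random_small_parameters():
    rng = np.random.default_rng(0)
    for _ in range(300):
        N = int(rng.integers(1, 21))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        got = hypergeom_upper_tail(k, K, n, N)
        assert got == pytest.approx(enumerate_upper_tail(k, K, n, N), rel=1e-12)


def test_matches_scipy_sf_at_scale():
    # independent library route on a realistic universe size
    for (k, K, n, N) in [(30, 50, 300, 2000), (1, 40, 50, 10000), (12, 26, 272, 1906)]:
        assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
            stats.hypergeom.sf(k - 1, N, K, n), rel=1e-10)


@pytest.mark.parametrize("bounds", [(-1, 5, 5, 10), (6, 5, 5, 10), (0, 11, 5, 10),
                                    (0, 5, 11, 10)])
def test_bound_violations_named(bounds):
    with pytest.raises(ValueError, match="require"):
        hypergeom_upper_tail(*bounds)


def test_bh_single_p_identity():
    assert bh_adjust([0.04]).tolist() == [0.04]


def test_bh_hand_computed_step_up():
    q = bh_adjust([0.01, 0.02, 0.03])
    assert q == pytest.approx([0.03, 0.03, 0.03])


def test_bh_matches_statsmodels_on_random_vectors():
    rng = np.random.default_rng(1)
    for _ in range(50):
        p = rng.uniform(1e-8, 1.0, size=int(rng.integers(1, 40)))
        got = bh_adjust(p)
        want = multipletests(p, method="fdr_bh")[1]
        assert got == pytest.approx(want, rel=1e-12)
        # order statistics of q monotone in order statistics of p
        order = np.argsort(p)
        assert np.all(np.diff(got[order]) >= -1e-15)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.0, 0.5])


def test_enrich_terms_exact_case():
    universe = {f"g{i}" for i in range(10)}
    term_genes = frozenset(list(sorted(universe))[:5])
    ann = [TermAnnotation("T1", "five genes", term_genes)]
    (res,) = enrich_terms(term_genes, ann, universe)
    assert res.p_value == pytest.approx(1 / 252, rel=1e-12)
    assert (res.overlap_k, res.term_size_K, res.query_size_n, res.universe_size_N) \
        == (5, 5, 5, 10)


def test_disjoint_term_p_is_one():
    universe = {f"g{i}" for i in range(10)}
    ann = [TermAnnotation("T1", "other", frozenset(["g8", "g9"]))]
    (res,) = enrich_terms({"g0", "g1"}, ann, universe)
    assert res.overlap_k == 0 and res.p_value == 1.0


def test_enrich_table_matches_per_term_loop():
    rng = np.random.default_rng(2)
    universe = [f"g{i}" for i in range(400)]
    anns = [TermAnnotation(f"T{t:02d}", "t",
                           frozenset(rng.choice(universe, size=int(rng.integers(5, 60)),
                                                replace=False)))
            for t in range(25)]
    query = set(rng.choice(universe, size=50, replace=False))
    results = enrich_terms(query, anns, set(universe))
    by_term = {r.term: r for r in results}
    for ann in anns:
        tg = ann.genes & set(universe)
        k = len(tg & query)
        want = hypergeom_upper_tail(k, len(tg), len(query), 400)
        assert by_term[ann.term].p_value == pytest.approx(want, rel=1e-12)
    # sorted ascending by p with term-id tie-break
    keys = [(r.p_value, r.term) for r in results]
    assert keys == sorted(keys)
    assert [r.term for r in top_terms(results, 6)] == [r.term for r in results[:6]]


def test_adding_annotated_gene_never_raises_p():
    universe = {f"g{i}" for i in range(50)}
    ann = [TermAnnotation("T1", "t", frozenset({f"g{i}" for i in range(10)}))]
    query = {"g0", "g20", "g21"}
    p0 = enrich_terms(query, ann, universe)[0].p_value
    p1 = enrich_terms(query | {"g1"}, ann, universe)[0].p_value
    assert p1 <= p0


def test_enrich_input_validation():
    with pytest.raises(ValueError, match="empty query"):
        enrich_terms(set(), [], {"a"})
    with pytest.raises(ValueError, match="subset"):
        enrich_terms({"b"}, [], {"a"})


def test_gmt_round_trip(tmp_path):
    p = tmp_path / "t.gmt"
    p.write_text("T1\tdesc one\tg1\tg2\tg3\nT2\tdesc two\tg9\n")
    t1, t2 = read_gmt(p)
    assert t1.genes == frozenset({"g1", "g2", "g3"})
    assert (t2.term, t2.name, t2.genes) == ("T2", "desc two", frozenset({"g9"}))
    p.write_text("T1\tonly desc\n")
    with pytest.raises(ValueError, match="GMT"):
        read_gmt(p)


def test_null_queries_are_calibrated():
    """Uniform null queries produce p < alpha at a rate within 3 binomial
    standard errors of alpha."""
    rng = np.random.default_rng(3)
    universe = [f"g{i}" for i in range(300)]
    ann = [TermAnnotation("T", "t", frozenset(universe[:30]))]
    alpha = 0.05
    n_rep = 1000
    hits = 0
    for _ in range(n_rep):
        query = set(rng.choice(universe, size=40, replace=False))
        p = enrich_terms(query, ann, set(universe))[0].p_value
        hits += p < alpha
    rate = hits / n_rep
    se = math.sqrt(alpha * (1 - alpha) / n_rep)
    # discrete test is conservative: the rate may fall below, never far above
    assert rate <= alpha + 3 * se
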