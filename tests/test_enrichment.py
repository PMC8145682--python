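"""Tests for ontology handling and binomial enrichment."""

from fractions import Fraction

import numpy as np
import pytest

from orthoprofiler.enrichment import (AnnotationSet, binomial_test, enrich,
                                      load_ontology, propagate, random_control,
                                      term_depth, tissue_enrich, write_report)

CHAIN = [("a", "root"), ("b", "a"), ("c", "b"), ("d", "c")]
DIAMOND = [("D", "B"), ("D", "C"), ("B", "A"), ("C", "A")]


def exact_binomial_tail(k, n, p0, tail):
    """Independent oracle: exact rational tail sum with Fraction arithmetic."""
    from math import comb

    p = Fraction(p0).limit_denominator(10**9)
    q = 1 - p
    rng = range(k, n + 1) if tail == "over" else range(0, k + 1)
    total = sum(comb(n, i) * p**i * q**(n - i) for i in rng)
    return float(total)


class TestLoadOntology:
    def test_chain(self):
        dag = load_ontology([("a", "root"), ("b", "a"), ("c", "b")])
        assert len(dag.terms) == 4
        assert dag.roots == {"root"}

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            load_ontology([("A", "B"), ("B", "A")])

    def test_diamond_valid_single_root(self):
        dag = load_ontology(DIAMOND)
        assert dag.roots == {"A"}

    def test_edge_tsv_file(self, tmp_path):
        p = tmp_path / "dag.tsv"
        p.write_text("child\tparent\na\troot\nb\ta\n")
        dag = load_ontology(p)
        assert dag.terms == {"root", "a", "b"}

    def test_minimal_obo_subset(self, tmp_path):
        p = tmp_path / "dag.obo"
        p.write_text("[Term]\nid: a\nis_a: root ! the root\n\n[Term]\nid: b\nis_a: a\n")
        dag = load_ontology(p)
        assert dag.terms == {"root", "a", "b"}
        assert term_depth(dag, "b") == 2

    def test_bad_tsv_row_raises(self, tmp_path):
        p = tmp_path / "dag.tsv"
        p.write_text("a\troot\nb\n")
        with pytest.raises(ValueError, match="line 2"):
            load_ontology(p)


class TestTermDepth:
    def test_root_is_zero(self):
        dag = load_ontology(CHAIN)
        assert term_depth(dag, "root") == 0

    def test_chain_depths(self):
        dag = load_ontology(CHAIN)
        assert term_depth(dag, "d") == 4

    def test_diamond_shortest_path(self):
        edges = DIAMOND + [("E", "D"), ("E", "A")]  # E: depth 1 via direct edge
        dag = load_ontology(edges)
        assert term_depth(dag, "D") == 2
        assert term_depth(dag, "E") == 1

    def test_unknown_term(self):
        with pytest.raises(KeyError):
            term_depth(load_ontology(CHAIN), "nope")


class TestPropagate:
    def test_leaf_of_chain_gets_ancestors(self):
        dag = load_ontology([("a", "root"), ("b", "a")])
        ann = propagate(dag, AnnotationSet.from_pairs([("g", "b")]))
        assert ann.gene_terms["g"] == {"b", "a", "root"}

    def test_idempotent(self):
        dag = load_ontology(CHAIN)
        once = propagate(dag, AnnotationSet.from_pairs([("g", "d")]))
        twice = propagate(dag, once)
        assert once.gene_terms == twice.gene_terms

    def test_empty_annotations(self):
        dag = load_ontology(CHAIN)
        assert propagate(dag, AnnotationSet.from_pairs([])).gene_terms == {}

    def test_unknown_term_listed(self):
        dag = load_ontology(CHAIN)
        with pytest.raises(ValueError, match="ghost"):
            propagate(dag, AnnotationSet.from_pairs([("g", "ghost")]))

    def test_reference_count_monotone_up_the_dag(self):
        """After propagation a parent's annotation count >= any child's."""
        rng = np.random.default_rng(0)
        edges = [(f"t{i}", f"t{(i - 1) // 2}") for i in range(1, 15)]  # binary tree
        dag = load_ontology(edges)
        pairs = [(f"g{j}", f"t{rng.integers(15)}") for j in range(50)]
        ann = propagate(dag, AnnotationSet.from_pairs(pairs))
        counts = {}
        for terms in ann.gene_terms.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        for child, parent in edges:
            assert counts.get(parent, 0) >= counts.get(child, 0)


class TestBinomialTest:
    def test_over_at_zero_is_one(self):
        assert binomial_test(0, 10, 0.3, "over") == 1.0

    def test_degenerate_p0(self):
        assert binomial_test(0, 10, 0.0, "over") == 1.0
        assert binomial_test(1, 10, 0.0, "over") == 0.0
        assert binomial_test(10, 10, 1.0, "under") == 1.0

    def test_documented_example(self):
        # P(X >= 3), X ~ Bin(10, 0.1) = 1 - sum_{i<3} C(10,i) 0.1^i 0.9^(10-i)
        assert binomial_test(3, 10, 0.1, "over") == pytest.approx(0.0701908, abs=1e-6)

    def test_domain_violations(self):
        with pytest.raises(ValueError):
            binomial_test(5, 3, 0.5, "over")
        with pytest.raises(ValueError):
            binomial_test(1, 3, 1.5, "over")
        with pytest.raises(ValueError):
            binomial_test(1, 3, 0.5, "sideways")

    @pytest.mark.parametrize("k,n,p0", [(3, 10, 0.1), (0, 5, 0.5), (17, 40, 0.3),
                                        (200, 400, 0.5), (5, 1000, 0.001)])
    def test_matches_exact_rational_oracle(self, k, n, p0):
        for tail in ("over", "under"):
            assert binomial_test(k, n, p0, tail) == pytest.approx(
                exact_binomial_tail(k, n, p0, tail), abs=1e-12)

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(123)
        n_draws = 100_000
        for k, n, p0 in [(3, 10, 0.1), (8, 20, 0.3), (2, 15, 0.2)]:
            draws = rng.binomial(n, p0, size=n_draws)
            for tail, emp in (("over", np.mean(draws >= k)), ("under", np.mean(draws <= k))):
                p = binomial_test(k, n, p0, tail)
                se = np.sqrt(max(p * (1 - p), 1e-12) / n_draws)
                assert abs(p - emp) < 3 * se + 1e-9


@pytest.fixture()
def flat_universe():
    """1000 genes, each annotated to leaf terms of a depth-4 chain forest."""
    edges = []
    for t in range(8):
        edges += [(f"c{t}_d{d}", f"c{t}_d{d - 1}" if d > 1 else "root") for d in range(1, 5)]
    dag = load_ontology(edges)
    genes = [f"g{i:04d}" for i in range(1000)]
    return dag, genes, edges


class TestEnrich:
    def test_sample_equal_reference_nothing_significant(self, flat_universe):
        dag, genes, _ = flat_universe
        rng = np.random.default_rng(1)
        pairs = [(g, f"c{rng.integers(8)}_d4") for g in genes]
        ann = propagate(dag, AnnotationSet.from_pairs(pairs))
        results = enrich(genes, genes, ann, dag, depth_range=(4, 4))
        assert results
        assert not any(r.significant for r in results)

    def test_planted_term_dominates(self, flat_universe):
        dag, genes, _ = flat_universe
        rng = np.random.default_rng(2)
        sample = genes[:20]
        pairs = [(g, "c0_d4") for g in sample]           # all 20 sample genes
        others = [g for g in genes if g not in sample]
        pairs += [(g, "c0_d4") for g in others if rng.random() < 0.05]
        pairs += [(g, f"c{1 + rng.integers(7)}_d4") for g in genes if rng.random() < 0.3]
        ann = propagate(dag, AnnotationSet.from_pairs(pairs))
        results = enrich(sample, genes, ann, dag, depth_range=(4, 4))
        top = results[0]
        assert top.term == "c0_d4"
        assert top.significant and top.direction == "over"
        # p is on the (K/N)^20 scale: astronomically small
        assert top.p_over < 1e-20

    def test_depth_filter_out_of_range_warns_and_empties(self):
        dag = load_ontology([("a", "root"), ("b", "a"), ("c", "b")])  # depths 0..3
        ann = propagate(dag, AnnotationSet.from_pairs([("g1", "c"), ("g2", "b")]))
        with pytest.warns(UserWarning, match="depth"):
            results = enrich(["g1"], ["g1", "g2"], ann, dag, depth_range=(4, 5))
        assert results == []

    def test_all_reported_depths_within_range(self, default_run):
        import pandas as pd
        for i in range(4):
            df = pd.read_csv(default_run / "enrichment" / f"cluster_{i}.tsv", sep="\t")
            assert df["depth"].between(4, 5).all()

    def test_sample_outside_reference_rejected(self, flat_universe):
        dag, genes, _ = flat_universe
        ann = propagate(dag, AnnotationSet.from_pairs([(genes[0], "c0_d4")]))
        with pytest.raises(ValueError, match="not in reference"):
            enrich(["stranger"], genes, ann, dag)
        with pytest.raises(ValueError, match="empty"):
            enrich([], genes, ann, dag)

    def test_adjusted_never_below_raw_and_capped(self, flat_universe):
        dag, genes, _ = flat_universe
        rng = np.random.default_rng(3)
        pairs = [(g, f"c{rng.integers(8)}_d4") for g in genes if rng.random() < 0.5]
        ann = propagate(dag, AnnotationSet.from_pairs(pairs))
        results = enrich(genes[:50], genes, ann, dag, depth_range=(1, 4))
        for r in results:
            assert r.p_adj_over >= r.p_over and r.p_adj_over <= 1.0
            assert r.p_adj_under >= r.p_under and r.p_adj_under <= 1.0

    def test_hypergeom_alternative_close_to_binomial(self, flat_universe):
        dag, genes, _ = flat_universe
        rng = np.random.default_rng(4)
        pairs = [(g, f"c{rng.integers(8)}_d4") for g in genes if rng.random() < 0.4]
        ann = propagate(dag, AnnotationSet.from_pairs(pairs))
        rb = enrich(genes[:30], genes, ann, dag, depth_range=(4, 4))
        rh = enrich(genes[:30], genes, ann, dag, depth_range=(4, 4), method="hypergeom")
        # small sample vs large reference: the two models nearly coincide
        for b, h in zip(sorted(rb, key=lambda r: r.term), sorted(rh, key=lambda r: r.term)):
            assert b.p_over == pytest.approx(h.p_over, rel=0.35, abs=0.02)


class TestTissueEnrich:
    def test_planted_tissue_detected(self):
        genes = [f"g{i}" for i in range(200)]
        rng = np.random.default_rng(5)
        sample = genes[:20]
        pairs = [(g, "kidney") for g in sample]
        pairs += [(g, "kidney") for g in genes[20:] if rng.random() < 0.1]
        pairs += [(g, "liver") for g in genes if rng.random() < 0.2]
        ann = AnnotationSet.from_pairs(pairs)
        results = tissue_enrich(sample, genes, ann)
        assert results[0].term == "kidney"
        assert results[0].significant and results[0].direction == "over"

    def test_single_tissue_universe_never_significant(self):
        genes = [f"g{i}" for i in range(50)]
        ann = AnnotationSet.from_pairs([(g, "everywhere") for g in genes])
        results = tissue_enrich(genes[:10], genes, ann)
        assert len(results) == 1
        assert results[0].p_over == 1.0
        assert not results[0].significant

    def test_uniform_labels_rarely_significant(self):
        """With uniformly random tissue labels the Bonferroni-corrected
        analysis stays quiet in at least 95% of seeded trials."""
        genes = [f"g{i}" for i in range(300)]
        hits = 0
        n_trials = 40
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            pairs = [(g, f"tissue{rng.integers(6)}") for g in genes]
            ann = AnnotationSet.from_pairs(pairs)
            results = tissue_enrich(list(rng.choice(genes, 30, replace=False)), genes, ann)
            hits += any(r.significant for r in results)
        assert hits / n_trials <= 0.05


class TestRandomControl:
    def test_empty_annotations_all_zero(self, flat_universe):
        dag, genes, _ = flat_universe
        ann = AnnotationSet(gene_terms={}, propagated=True)
        counts, total = random_control(genes, ann, dag, set_size=50, n_reps=5, seed=0)
        assert counts == [0, 0, 0, 0, 0] and total == 0

    def test_set_size_too_large(self, flat_universe):
        dag, genes, _ = flat_universe
        ann = AnnotationSet(gene_terms={}, propagated=True)
        with pytest.raises(ValueError, match="set_size"):
            random_control(genes[:10], ann, dag, set_size=20, n_reps=1, seed=0)

    def test_deterministic_given_seed(self, flat_universe):
        dag, genes, _ = flat_universe
        rng = np.random.default_rng(6)
        pairs = [(g, f"c{rng.integers(8)}_d4") for g in genes if rng.random() < 0.2]
        ann = propagate(dag, AnnotationSet.from_pairs(pairs))
        a = random_control(genes, ann, dag, set_size=100, n_reps=5, seed=9,
                           depth_range=(4, 4))
        b = random_control(genes, ann, dag, set_size=100, n_reps=5, seed=9,
                           depth_range=(4, 4))
        assert a == b

    def test_planted_universe_sampled_at_random(self, flat_universe):
        """Random draws from a universe with one strongly planted term pick
        up the planted genes only by hypergeometric overlap, so significant
        calls are rare but the planted term is the only one that ever fires."""
        dag, genes, _ = flat_universe
        rng = np.random.default_rng(7)
        planted_genes = genes[:60]
        pairs = [(g, "c0_d4") for g in planted_genes]
        pairs += [(g, f"c{rng.integers(8)}_d4") for g in genes if rng.random() < 0.1]
        ann = propagate(dag, AnnotationSet.from_pairs(pairs))
        counts, total = random_control(genes, ann, dag, set_size=100, n_reps=20,
                                       seed=11, depth_range=(4, 4))
        assert len(counts) == 20
        assert total <= 20  # occasional hits at most; no runaway signal


def test_write_report_round_trip_columns(tmp_path, flat_universe):
    import pandas as pd
    dag, genes, _ = flat_universe
    rng = np.random.default_rng(8)
    pairs = [(g, f"c{rng.integers(8)}_d4") for g in genes if rng.random() < 0.3]
    ann = propagate(dag, AnnotationSet.from_pairs(pairs))
    results = enrich(genes[:40], genes, ann, dag, depth_range=(4, 4))
    out = tmp_path / "report.tsv"
    write_report(results, out)
    df = pd.read_csv(out, sep="\t")
    assert list(df.columns) == ["term", "depth", "k", "n", "K", "N", "p_over",
                                "p_under", "p_adj_over", "p_adj_under",
                                "significant", "direction"]
    assert len(df) == len(results)
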