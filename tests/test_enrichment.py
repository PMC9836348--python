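import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgascreen.enrichment import (
    AnnotationSet,
    bh_fdr,
    curate_rank,
    enrich_gene_set,
    hypergeom_test,
    strength,
)
from sgascreen.simulate import ValidationError


def brute_force_upper_tail(k, n, K, N):
    """P(X >= k) by enumerating every n-subset of an N-element universe.

    The first K elements are 'annotated'; completely independent of any
    distribution function.
    """
    total = 0
    hits = 0
    for subset in itertools.combinations(range(N), n):
        total += 1
        marked = sum(1 for x in subset if x < K)
        if marked >= k:
            hits += 1
    return hits / total


class TestHypergeomTest:
    def test_zero_overlap_has_pvalue_one(self):
        assert hypergeom_test(0, 5, 3, 20) == 1.0

    def test_perfect_draw_probability(self):
        assert hypergeom_test(5, 5, 5, 20) == pytest.approx(1 / math.comb(20, 5))

    def test_small_table_matches_enumeration(self):
        assert hypergeom_test(2, 3, 4, 10) == pytest.approx(1 / 3)
        assert brute_force_upper_tail(2, 3, 4, 10) == pytest.approx(1 / 3)

    def test_matches_enumeration_for_all_small_tables(self):
        for N in range(1, 13):
            for n in range(0, N + 1):
                subsets = list(itertools.combinations(range(N), n))
                for K in range(0, N + 1):
                    marked = [sum(1 for x in s if x < K) for s in subsets]
                    for k in range(max(0, n - (N - K)), min(n, K) + 1):
                        expected = sum(1 for m in marked if m >= k) / len(subsets)
                        assert hypergeom_test(k, n, K, N) == pytest.approx(
                            expected, abs=1e-12
                        )

    def test_equals_one_sided_fisher(self):
        from scipy.stats import fisher_exact

        k, n, K, N = 7, 30, 50, 400
        table = [[k, n - k], [K - k, N - K - (n - k)]]
        _, p_fisher = fisher_exact(table, alternative="greater")
        assert hypergeom_test(k, n, K, N) == pytest.approx(p_fisher, rel=1e-9)

    @pytest.mark.parametrize("args", [(5, 3, 10, 20), (4, 5, 3, 20), (3, 5, 4, 4)])
    def test_impossible_tables_rejected(self, args):
        with pytest.raises(ValidationError):
            hypergeom_test(*args)

    def test_p_nonincreasing_in_overlap(self):
        ps = [hypergeom_test(k, 10, 20, 100) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestStrength:
    def test_observed_equals_expected_gives_zero(self):
        # k = n*K/N exactly
        assert strength(4, 20, 20, 100) == 0.0

    def test_fivefold_enrichment(self):
        assert strength(4, 100, 40, 5000) == pytest.approx(math.log10(5))

    def test_doubling_overlap_adds_log10_two(self):
        a = strength(4, 100, 40, 5000)
        b = strength(8, 100, 40, 5000)
        assert b - a == pytest.approx(math.log10(2))

    def test_increasing_in_overlap(self):
        vals = [strength(k, 50, 30, 500) for k in range(1, 31)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_zero_overlap_undefined(self):
        with pytest.raises(ValidationError):
            strength(0, 10, 5, 100)


class TestBhFdr:
    def test_single_pvalue_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        # p(i) * m / i = .04, .04, .04, .04 after monotonicity
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_tied_pvalues_share_adjustment(self):
        out = bh_fdr([0.02, 0.02, 0.02])
        assert out == pytest.approx([0.02] * 3)

    def test_known_mixed_vector(self):
        out = bh_fdr([0.005, 0.04, 0.2, 0.8])
        assert out == pytest.approx([0.02, 0.08, 0.8 * 4 / 12, 0.8])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_input_permutation(self, ps):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ps))
        direct = bh_fdr(ps)
        permuted = bh_fdr([ps[i] for i in perm])
        assert np.allclose(direct[perm], permuted)

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan]):
            with pytest.raises(ValidationError):
                bh_fdr(bad)


def toy_annotations():
    # 20-gene background; term T annotates 5 genes
    genes = [f"g{i:02d}" for i in range(20)]
    pairs = [(g, "T") for g in genes[:5]]
    pairs += [(g, "OTHER") for g in genes]
    return AnnotationSet.from_pairs(pairs)


class TestEnrichGeneSet:
    def test_query_equal_to_background_is_null(self):
        ann = toy_annotations()
        rows = enrich_gene_set(ann.background, ann)
        assert (rows["strength"] == 0).all()
        assert rows["p"].to_numpy() == pytest.approx(1.0)

    def test_toy_cluster_fully_annotated(self):
        ann = toy_annotations()
        rows = enrich_gene_set([f"g{i:02d}" for i in range(5)], ann).set_index("term")
        assert rows.loc["T", "p"] == pytest.approx(1 / math.comb(20, 5))
        assert rows.loc["T", "strength"] == pytest.approx(math.log10(4))

    def test_unannotated_terms_absent(self):
        ann = toy_annotations()
        rows = enrich_gene_set([f"g{i:02d}" for i in range(10, 15)], ann)
        assert "T" not in set(rows["term"])

    def test_genes_outside_background_dropped_with_count(self):
        ann = toy_annotations()
        rows = enrich_gene_set(["g00", "g01", "nope"], ann)
        assert rows.attrs["n_dropped"] == 1
        assert rows.set_index("term").loc["T", "n"] == 2

    def test_custom_background(self):
        ann = toy_annotations()
        bg = {f"g{i:02d}" for i in range(20)} | {f"x{i}" for i in range(20)}
        rows = enrich_gene_set([f"g{i:02d}" for i in range(5)], ann,
                               background_mode="custom", custom_background=bg)
        assert rows.set_index("term").loc["T", "N"] == 40

    def test_false_positive_rate_controlled_on_null_sets(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:03d}" for i in range(300)]
        pairs = []
        for t in range(40):
            members = rng.choice(genes, size=15, replace=False)
            pairs += [(g, f"T{t:02d}") for g in members]
        ann = AnnotationSet.from_pairs(pairs, background=genes)
        n_sig = n_tests = 0
        for draw in range(200):
            query = rng.choice(genes, size=20, replace=False)
            rows = enrich_gene_set(query, ann)
            n_sig += int((rows["fdr"] <= 0.05).sum())
            n_tests += len(rows)
        assert n_sig / max(n_tests, 1) <= 0.08


class TestCurateRank:
    def rows(self):
        ann = AnnotationSet.from_pairs(
            [("g1", "A"), ("g2", "A"), ("g3", "A"),
             ("g1", "B"), ("g2", "B"), ("g3", "B"),
             ("g4", "C"), ("g5", "C"), ("g6", "C"), ("g7", "C")]
            + [(f"g{i}", "BG") for i in range(1, 31)]
        )
        query = [f"g{i}" for i in range(1, 8)]
        return enrich_gene_set(query, ann), ann

    def test_minimum_gene_filter(self):
        rows, ann = self.rows()
        kept = curate_rank(rows, annotations=ann, fdr_max=1.0, min_genes=4, top_n=None)
        assert set(kept["term"]) <= {"C", "BG"}
        assert (kept["k"] >= 4).all()

    def test_display_cap(self):
        ann = AnnotationSet.from_pairs(
            [(f"g{i}", f"T{t:02d}") for t in range(25) for i in range(5)]
        )
        rows = enrich_gene_set([f"g{i}" for i in range(5)], ann)
        kept = curate_rank(rows, annotations=ann, fdr_max=1.0, top_n=10)
        assert len(kept) == 10

    def test_redundant_term_dropped_by_jaccard(self):
        rows, ann = self.rows()
        kept = curate_rank(rows, annotations=ann, fdr_max=1.0,
                           redundancy_jaccard=0.9, top_n=None)
        terms = set(kept["term"])
        assert ("A" in terms) != ("B" in terms)  # identical gene sets: only one kept

    def test_sorted_by_strength_descending(self):
        rows, ann = self.rows()
        kept = curate_rank(rows, annotations=ann, fdr_max=1.0, top_n=None)
        s = kept["strength"].to_numpy()
        assert (np.diff(s) <= 1e-12).all()

    def test_blocklist_removes_vague_terms(self):
        rows, ann = self.rows()
        kept = curate_rank(rows, annotations=ann, fdr_max=1.0,
                           term_blocklist={"BG"}, top_n=None)
        assert "BG" not in set(kept["term"])


class TestAnnotationIO:
    def test_two_column_tsv_round_trip(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("gene\tterm\ng1\tT1\ng2\tT1\ng2\tT2\n")
        ann = AnnotationSet.from_tsv(path)
        assert ann.term_genes == {"T1": {"g1", "g2"}, "T2": {"g2"}}
        assert ann.background == {"g1", "g2"}

    def test_gaf_columns_parsed(self, tmp_path):
        path = tmp_path / "ann.gaf"
        path.write_text(
            "!gaf-version: 2.2\n"
            "SGD\tS0001\tGENE1\t\tGO:0001\tref\tIDA\t\tP\t\t\tgene\ttaxon:4932\t1\tSGD\n"
            "SGD\tS0002\tGENE2\t\tGO:0001\tref\tIDA\t\tP\t\t\tgene\ttaxon:4932\t1\tSGD\n"
        )
        ann = AnnotationSet.from_gaf(path)
        assert ann.term_genes == {"GO:0001": {"S0001", "S0002"}}

    def test_annotated_gene_outside_background_rejected(self):
        with pytest.raises(ValidationError):
            AnnotationSet.from_pairs([("g1", "T")], background={"g2"})
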