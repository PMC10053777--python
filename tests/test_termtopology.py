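"""Enrichment-map construction, set coefficients, term-redundancy reduction."""

import numpy as np
import pandas as pd
import pytest

from mixturetox.diffexpr import ContrastResult, DegSet
from mixturetox.enrichment import GeneSet, GeneSetCollection
from mixturetox.termtopology import (
    build_enrichment_map,
    cluster_mean_lfc,
    jaccard_distance,
    overlap_coefficient,
    reduce_terms,
)


def _collection(named_sets, namespace="BP"):
    return GeneSetCollection(
        GeneSet(tid, tid, namespace, frozenset(s)) for tid, s in named_sets.items()
    )


def _rows(term_ids, collection, query_id="q", ratio=None):
    return pd.DataFrame(
        {
            "term_id": term_ids,
            "name": term_ids,
            "namespace": [collection[t].namespace for t in term_ids],
            "query_id": query_id,
            "p_adj": 0.01,
            "ratio": ratio if ratio is not None else 2.0,
            "significant": True,
        }
    )


class TestSetCoefficients:
    def test_overlap_identical_and_disjoint(self):
        assert overlap_coefficient({"a", "b"}, {"a", "b"}) == 1.0
        assert overlap_coefficient({"a"}, {"b", "c"}) == 0.0

    def test_overlap_direct_arithmetic(self):
        assert overlap_coefficient({"a", "b", "c", "d"}, {"c", "d", "e"}) == pytest.approx(2 / 3)

    def test_overlap_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_coefficient(set(), {"a"})

    def test_jaccard_identical_and_disjoint(self):
        assert jaccard_distance({"a", "b"}, {"a", "b"}) == 0.0
        assert jaccard_distance({"a"}, {"b"}) == 1.0

    def test_jaccard_direct_arithmetic(self):
        a = set(range(1, 11))
        b = set(range(1, 7))
        assert jaccard_distance(a, b) == pytest.approx(0.4)

    def test_jaccard_both_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            jaccard_distance(set(), set())

    def test_equal_size_sets_unit_values_iff_identical(self):
        """For |A|=|B|: overlap==1 and jaccard==0 exactly when A == B."""
        rng = np.random.default_rng(0)
        pool = list(range(40))
        for _ in range(200):
            a = frozenset(rng.choice(pool, 8, replace=False))
            b = frozenset(rng.choice(pool, 8, replace=False))
            both_unit = overlap_coefficient(a, b) == 1.0 and jaccard_distance(a, b) == 0.0
            assert both_unit == (a == b)


class TestBuildEnrichmentMap:
    def test_no_edges_all_singletons(self):
        sets = {f"T{i}": {f"g{10*i+j}" for j in range(5)} for i in range(4)}
        coll = _collection(sets)
        g = build_enrichment_map(_rows(list(sets), coll), coll, threshold=0.4)
        assert g.graph.number_of_edges() == 0
        assert g.n_clusters() == 4

    def test_nested_terms_single_cluster(self):
        sets = {
            "T1": {"a", "b"},
            "T2": {"a", "b", "c", "d"},
            "T3": {"a", "b", "c", "d", "e", "f"},
        }
        coll = _collection(sets)
        g = build_enrichment_map(_rows(list(sets), coll), coll, threshold=0.4)
        assert g.n_clusters() == 1
        for u, v, d in g.graph.edges(data=True):
            assert d["coefficient"] == 1.0

    def test_components_match_union_find_oracle(self):
        """Random 50-term graphs: clusters equal brute-force union-find."""
        rng = np.random.default_rng(7)
        pool = [f"g{i}" for i in range(120)]
        for trial in range(20):
            sets = {
                f"T{i}": set(rng.choice(pool, int(rng.integers(4, 25)), replace=False))
                for i in range(50)
            }
            coll = _collection(sets)
            g = build_enrichment_map(_rows(list(sets), coll), coll, threshold=0.5)
            # independent union-find on the brute-force thresholded edge list
            parent = {t: t for t in sets}

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            ids = list(sets)
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    a, b = sets[ids[i]], sets[ids[j]]
                    if len(a & b) / min(len(a), len(b)) >= 0.5:
                        parent[find(ids[i])] = find(ids[j])
            oracle = {}
            for t in ids:
                oracle.setdefault(find(t), set()).add(t)
            ours = {}
            for (tid, _q), cid in g.clusters.items():
                ours.setdefault(cid, set()).add(tid)
            assert sorted(map(sorted, oracle.values())) == sorted(map(sorted, ours.values()))

    def test_raising_threshold_never_merges_components(self):
        rng = np.random.default_rng(3)
        pool = [f"g{i}" for i in range(60)]
        sets = {
            f"T{i}": set(rng.choice(pool, int(rng.integers(5, 20)), replace=False))
            for i in range(25)
        }
        coll = _collection(sets)
        rows = _rows(list(sets), coll)
        counts = [
            build_enrichment_map(rows, coll, threshold=t).n_clusters()
            for t in (0.2, 0.4, 0.6, 0.8, 1.01)
        ]
        assert counts == sorted(counts)

    def test_multi_query_nodes_and_annotation(self):
        sets = {"T1": {"a", "b", "c"}, "T2": {"a", "b", "c", "d"}}
        coll = _collection(sets)
        rows = pd.concat(
            [_rows(list(sets), coll, "q1"), _rows(["T1"], coll, "q2")], ignore_index=True
        )
        g = build_enrichment_map(rows, coll, threshold=0.4)
        assert g.graph.number_of_nodes() == 3
        assert g.n_clusters() == 1
        big = g.annotatable_clusters()
        assert big == []  # cluster has exactly 3 terms, needs > 3
        g.annotate(0, "theme")
        assert g.node_table()["theme"].eq("theme").all()


class TestReduceTerms:
    def test_no_merge_when_all_distant(self):
        sets = {f"T{i}": {f"g{20*i+j}" for j in range(10)} for i in range(5)}
        coll = _collection(sets)
        out = reduce_terms({"trt": _rows(list(sets), coll)}, coll)
        assert len(out) == 5
        assert set(out.matrix.index) == set(sets)

    def test_duplicate_terms_merge_with_lexicographic_name(self):
        genes = {f"g{i}" for i in range(12)}
        coll = _collection({"TB": genes, "TA": genes})
        out = reduce_terms({"trt": _rows(["TB", "TA"], coll)}, coll)
        assert len(out) == 1
        assert out.matrix.index[0] == "TA"
        assert set(out.manifest["term_id"]) == {"TA", "TB"}

    def test_smallest_constituent_names_merged_term(self):
        coll = _collection({"TBIG": {f"g{i}" for i in range(12)},
                            "TSMALL": {f"g{i}" for i in range(10)}})
        out = reduce_terms({"trt": _rows(["TBIG", "TSMALL"], coll)}, coll)
        assert len(out) == 1
        assert out.matrix.index[0] == "TSMALL"

    def test_recovers_planted_families(self):
        """4 families of 5 near-duplicate terms merge into exactly 4 rows."""
        rng = np.random.default_rng(11)
        sets = {}
        families = {}
        for f in range(4):
            core = {f"f{f}_g{i}" for i in range(30)}
            for m in range(5):
                tid = f"F{f}M{m}"
                drop = set(rng.choice(sorted(core), 3, replace=False))
                sets[tid] = (core - drop) | {f"f{f}_extra{m}"}
                families[tid] = f
        coll = _collection(sets)
        out = reduce_terms({"trt": _rows(list(sets), coll)}, coll)
        assert len(out) == 4
        groups = out.manifest.groupby("merged_term")["term_id"].apply(set)
        recovered = sorted(map(sorted, groups))
        expected = sorted(
            sorted(t for t, f in families.items() if f == fam) for fam in range(4)
        )
        assert recovered == expected

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(5)
        pool = [f"g{i}" for i in range(80)]
        sets = {
            f"T{i}": set(rng.choice(pool, int(rng.integers(8, 25)), replace=False))
            for i in range(15)
        }
        coll = _collection(sets)
        rows = _rows(list(sets), coll, ratio=list(np.linspace(5, 1, 15)))
        shuffled = rows.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = reduce_terms({"trt": rows}, coll)
        b = reduce_terms({"trt": shuffled}, coll)
        pd.testing.assert_frame_equal(a.matrix, b.matrix)

    def test_merged_constituents_within_distance(self):
        rng = np.random.default_rng(6)
        pool = [f"g{i}" for i in range(60)]
        sets = {
            f"T{i}": set(rng.choice(pool, int(rng.integers(10, 30)), replace=False))
            for i in range(20)
        }
        coll = _collection(sets)
        out = reduce_terms({"trt": _rows(list(sets), coll)}, coll, merge_at=0.45)
        for _, grp in out.manifest.groupby("merged_term"):
            ids = list(grp["term_id"])
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    assert jaccard_distance(coll[ids[i]].genes, coll[ids[j]].genes) < 0.45

    def test_top_n_ranking_by_ratio(self):
        sets = {f"T{i}": {f"g{20*i+j}" for j in range(10)} for i in range(6)}
        coll = _collection(sets)
        rows = _rows(list(sets), coll, ratio=[6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        out = reduce_terms({"trt": rows}, coll, top_n=3)
        assert set(out.matrix.index) == {"T0", "T1", "T2"}

    def test_empty_input_empty_matrix(self):
        coll = _collection({"T0": {"a"}})
        out = reduce_terms({}, coll)
        assert len(out) == 0


class TestClusterMeanLfc:
    def _setup(self, lfc_by_gene):
        sets = {"T1": {"a", "b"}, "T2": {"b", "c"}}
        coll = _collection(sets)
        g = build_enrichment_map(_rows(list(sets), coll), coll, threshold=0.4)
        table = pd.DataFrame(
            {
                "log2FC": pd.Series(lfc_by_gene),
                "wald_stat": 0.0,
                "p": 0.01,
                "p_adj": 0.01,
            }
        )
        contrast = ContrastResult("t", "c", table)
        degs = DegSet(genes=frozenset(lfc_by_gene), direction={})
        return g, contrast, degs, coll

    def test_uniform_downregulation(self):
        g, contrast, degs, coll = self._setup({"a": -0.5, "b": -0.5, "c": -0.5})
        out = cluster_mean_lfc(g, 0, contrast, degs, coll)
        assert out["mean_lfc"] == pytest.approx(-0.5)
        assert out["frac_down"] == 1.0
        assert out["n_genes"] == 3

    def test_symmetric_values(self):
        g, contrast, degs, coll = self._setup({"a": 1.0, "b": -1.0})
        out = cluster_mean_lfc(g, 0, contrast, degs, coll)
        assert out["mean_lfc"] == pytest.approx(0.0)
        assert out["mean_abs_lfc"] == pytest.approx(1.0)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(4)
        lfc = {g: float(v) for g, v in zip("abcdef", rng.normal(size=6))}
        g, contrast, degs, coll = self._setup(lfc)
        out = cluster_mean_lfc(g, 0, contrast, degs, coll)
        union = (coll["T1"].genes | coll["T2"].genes) & set(degs.genes)
        vals = np.array([lfc[x] for x in union])
        assert out["mean_lfc"] == pytest.approx(vals.mean())
        assert out["mean_abs_lfc"] == pytest.approx(np.abs(vals).mean())
        assert out["frac_down"] == pytest.approx((vals < 0).mean())

    def test_empty_intersection_reports_empty(self):
        g, contrast, _, coll = self._setup({"a": 1.0})
        empty_degs = DegSet(genes=frozenset({"zz"}), direction={})
        out = cluster_mean_lfc(g, 0, contrast, empty_degs, coll)
        assert out["n_genes"] == 0
        assert np.isnan(out["mean_lfc"])
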