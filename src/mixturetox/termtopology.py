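"""Enrichment-map topology and term-redundancy reduction.

Two complementary views of a set of enriched terms:

* an enrichment-map graph — one node per (term, query set), an undirected
  edge wherever the overlap coefficient |A∩B| / min(|A|,|B|) of two terms'
  gene sets reaches a threshold (default 0.4), with connected components as
  term clusters and free-text annotation slots for manually assigned themes;
* a reduced term matrix for cross-treatment heatmaps — per treatment and
  namespace the top-N terms by enrichment ratio are pooled, complete-linkage
  clustered on Jaccard distance, merged below a distance cutoff (default
  0.45), and each merged group is named after its smallest constituent term.

Gene-level summaries of a cluster (mean |log2FC|, fraction down-regulated)
come from intersecting the union of its terms' genes with a contrast's DEGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .diffexpr import ContrastResult, DegSet
from .enrichment import GeneSetCollection

__all__ = [
    "TermGraph",
    "overlap_coefficient",
    "jaccard_distance",
    "build_enrichment_map",
    "reduce_terms",
    "cluster_mean_lfc",
]

EDGE_THRESHOLD = 0.4
MERGE_DISTANCE = 0.45
TOP_N = 60
ANNOTATE_MIN_TERMS = 3  # components larger than this get an annotation slot


def overlap_coefficient(a: set, b: set) -> float:
    """|A∩B| / min(|A|, |B|)."""
    if not a or not b:
        raise ValueError("overlap coefficient is undefined for an empty set")
    return len(set(a) & set(b)) / min(len(set(a)), len(set(b)))


def jaccard_distance(a: set, b: set) -> float:
    """1 - |A∩B| / |A∪B|."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard distance is undefined when both sets are empty")
    return 1.0 - len(a & b) / len(union)


@dataclass
class TermGraph:
    """Enriched terms as nodes, overlap-coefficient edges, component clusters."""

    graph: nx.Graph
    threshold: float
    clusters: dict = field(default_factory=dict)  # node -> cluster id
    annotations: dict = field(default_factory=dict)  # cluster id -> theme text

    def n_clusters(self) -> int:
        return len(set(self.clusters.values()))

    def cluster_nodes(self, cluster_id) -> list:
        return [n for n, c in self.clusters.items() if c == cluster_id]

    def annotatable_clusters(self) -> list:
        """Cluster ids with more than ANNOTATE_MIN_TERMS member terms."""
        sizes = pd.Series(list(self.clusters.values())).value_counts()
        return sorted(sizes.index[sizes > ANNOTATE_MIN_TERMS])

    def annotate(self, cluster_id, theme: str) -> None:
        if cluster_id not in set(self.clusters.values()):
            raise KeyError(f"no cluster {cluster_id!r}")
        self.annotations[cluster_id] = theme

    def edge_table(self) -> pd.DataFrame:
        rows = [(u, v, d["coefficient"]) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["source", "target", "coefficient"])

    def node_table(self) -> pd.DataFrame:
        rows = []
        for n, d in self.graph.nodes(data=True):
            rows.append(
                {
                    "node": n,
                    "term_id": d["term_id"],
                    "query_id": d["query_id"],
                    "namespace": d["namespace"],
                    "p_adj": d["p_adj"],
                    "ratio": d["ratio"],
                    "cluster": self.clusters[n],
                    "theme": self.annotations.get(self.clusters[n], ""),
                }
            )
        return pd.DataFrame(rows)

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for n in g.nodes:
            g.nodes[n]["cluster"] = str(self.clusters[n])
        nx.write_graphml(g, path)


def build_enrichment_map(
    rows: pd.DataFrame,
    collection: GeneSetCollection,
    threshold: float = EDGE_THRESHOLD,
) -> TermGraph:
    """Build the term network from significant enrichment rows.

    ``rows`` is the hypergeom_enrich output restricted to significant terms
    (any remaining non-significant rows are dropped here). Node identity is
    (term_id, query_id) so a term significant for several query sets appears
    once per query, colored by it; edges are computed on the terms' gene
    sets alone, so duplicate-term nodes are always connected.
    """
    if "significant" in rows.columns:
        rows = rows[rows["significant"]]
    g = nx.Graph()
    node_genes = {}
    for _, r in rows.iterrows():
        if r["term_id"] not in collection:
            raise KeyError(f"enrichment row references unknown term {r['term_id']!r}")
        node = (r["term_id"], r["query_id"])
        g.add_node(
            node,
            term_id=r["term_id"],
            query_id=r["query_id"],
            namespace=r["namespace"],
            p_adj=float(r["p_adj"]),
            ratio=float(r["ratio"]),
        )
        node_genes[node] = collection[r["term_id"]].genes
    nodes = list(g.nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            c = overlap_coefficient(node_genes[nodes[i]], node_genes[nodes[j]])
            if c >= threshold:
                g.add_edge(nodes[i], nodes[j], coefficient=c)
    clusters = {}
    for cid, comp in enumerate(sorted(nx.connected_components(g), key=lambda s: sorted(s)[0])):
        for n in comp:
            clusters[n] = cid
    return TermGraph(graph=g, threshold=threshold, clusters=clusters)


@dataclass
class ReducedTermMatrix:
    """Merged-term x treatment significance/ratio matrix with a manifest."""

    matrix: pd.DataFrame  # index merged term id; columns <trt>_significant, <trt>_ratio, <trt>_p_adj
    manifest: pd.DataFrame  # merged_term, constituent term_id, namespace

    def __len__(self):
        return len(self.matrix)


def _smallest_term(collection: GeneSetCollection, term_ids) -> str:
    """Fewest member genes; ties broken lexicographically by term id."""
    return min(term_ids, key=lambda t: (len(collection[t].genes), t))


def reduce_terms(
    per_treatment_rows: dict[str, pd.DataFrame],
    collection: GeneSetCollection,
    top_n: int = TOP_N,
    merge_at: float = MERGE_DISTANCE,
    *,
    pool_namespaces: bool = False,
) -> ReducedTermMatrix:
    """Redundancy-reduced cross-treatment term matrix.

    Per treatment and namespace, the ``top_n`` significant terms by
    enrichment ratio are pooled across treatments; pooled terms are
    complete-linkage clustered on pairwise Jaccard distance of their gene
    sets and groups below ``merge_at`` are combined, each named after its
    smallest constituent. The matrix reports, per treatment, whether any
    constituent was significant, the best (max) ratio, and the best (min)
    adjusted p. Merging is within namespace unless ``pool_namespaces``.
    """
    frames = []
    for trt, rows in per_treatment_rows.items():
        r = rows[rows["significant"]] if "significant" in rows.columns else rows
        r = r.assign(treatment=trt)
        top = (
            r.sort_values(["ratio", "term_id"], ascending=[False, True])
            .groupby("namespace", group_keys=False)
            .head(top_n)
        )
        frames.append(top)
    if not frames or all(len(f) == 0 for f in frames):
        empty = pd.DataFrame()
        return ReducedTermMatrix(matrix=empty, manifest=pd.DataFrame(
            columns=["merged_term", "term_id", "namespace"]))
    pooled = pd.concat(frames, ignore_index=True)

    ns_key = (lambda _: "pooled") if pool_namespaces else (lambda ns: ns)
    merged_groups: list[list[str]] = []
    for ns, block in sorted(pooled.groupby(pooled["namespace"].map(ns_key))):
        term_ids = sorted(block["term_id"].unique())
        if len(term_ids) == 1:
            merged_groups.append(term_ids)
            continue
        gsets = [collection[t].genes for t in term_ids]
        m = len(term_ids)
        dist = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                dist[i, j] = dist[j, i] = jaccard_distance(gsets[i], gsets[j])
        Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
        # strict "< merge_at" cut
        labels = hierarchy.fcluster(Z, t=np.nextafter(merge_at, 0), criterion="distance")
        for lab in np.unique(labels):
            merged_groups.append([term_ids[i] for i in np.where(labels == lab)[0]])

    treatments = list(per_treatment_rows)
    sig = pooled.set_index(["treatment", "term_id"])
    records, manifest = [], []
    for group in merged_groups:
        name = _smallest_term(collection, group)
        rec = {"merged_term": name, "namespace": collection[name].namespace,
               "n_constituents": len(group)}
        for trt in treatments:
            hits = [t for t in group if (trt, t) in sig.index]
            rec[f"{trt}_significant"] = bool(hits)
            rec[f"{trt}_ratio"] = max((sig.loc[(trt, t), "ratio"] for t in hits), default=np.nan)
            rec[f"{trt}_p_adj"] = min((sig.loc[(trt, t), "p_adj"] for t in hits), default=np.nan)
        records.append(rec)
        for t in group:
            manifest.append({"merged_term": name, "term_id": t,
                             "namespace": collection[t].namespace})
    matrix = pd.DataFrame(records).set_index("merged_term").sort_index()
    if matrix.index.has_duplicates:
        raise RuntimeError("merged-term names collide; term ids are not unique by size+lexicographic rule")
    return ReducedTermMatrix(matrix=matrix, manifest=pd.DataFrame(manifest))


def cluster_mean_lfc(
    term_graph: TermGraph,
    cluster_id,
    contrast: ContrastResult,
    degs: DegSet,
    collection: GeneSetCollection,
) -> dict:
    """Gene-level log2FC summary of one term cluster.

    The gene set is the union of the cluster's terms' members intersected
    with the contrast's DEGs; reports mean |log2FC|, signed mean, size, and
    the fraction with log2FC < 0. An empty intersection reports n_genes=0
    with NaN summaries rather than erroring.
    """
    nodes = term_graph.cluster_nodes(cluster_id)
    if not nodes:
        raise KeyError(f"no cluster {cluster_id!r} in graph")
    genes: set = set()
    for n in nodes:
        genes |= set(collection[term_graph.graph.nodes[n]["term_id"]].genes)
    genes &= set(degs.genes)
    if not genes:
        return {"mean_abs_lfc": np.nan, "mean_lfc": np.nan, "n_genes": 0, "frac_down": np.nan}
    lfc = contrast.table["log2FC"].reindex(sorted(genes)).dropna()
    return {
        "mean_abs_lfc": float(lfc.abs().mean()),
        "mean_lfc": float(lfc.mean()),
        "n_genes": int(lfc.size),
        "frac_down": float((lfc < 0).mean()),
    }
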