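"""GO-term clustering by Wang semantic similarity and subset contrasts.

Gene annotations are propagated to all ontology ancestors (is_a / part_of),
terms annotated to fewer than two reference genes are dropped, and the
remaining terms are clustered per namespace by average-linkage hierarchical
clustering on 1 - similarity, with the tree cut into a fixed number of
clusters (20 by default). Per cluster, the contribution of a gene subset is
the percentage of its genes annotated to at least one member term; subset
differences are tested with the two-sided Fisher exact test.

The Wang measure scores a term pair by the semantic contributions of their
shared ancestors: within a term's ancestor DAG, an ancestor's S-value is
the maximal product of edge weights (0.8 for is_a, 0.6 for part_of) along
a path down to the term itself, and similarity is the ratio of summed
shared S-values to the two terms' total semantic values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class OntologyGraph:
    """Directed acyclic term graph; edges run child -> parent."""

    graph: nx.MultiDiGraph
    namespaces: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_obo(cls, path) -> "OntologyGraph":
        g = obonet.read_obo(path)
        namespaces = {t: data.get("namespace", "biological_process")
                      for t, data in g.nodes(data=True)}
        return cls(graph=g, namespaces=namespaces)

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str, str]],
                   namespaces: dict[str, str] | None = None) -> "OntologyGraph":
        """Build from (child, parent, relation) triples; relation in is_a/part_of."""
        g = nx.MultiDiGraph()
        for child, parent, rel in edges:
            g.add_edge(child, parent, key=rel)
        terms = set(g.nodes)
        ns = namespaces or {t: "biological_process" for t in terms}
        og = cls(graph=g, namespaces=ns)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology graph must be acyclic")
        return og

    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        """All ancestors reachable via child->parent edges (term excluded)."""
        return nx.descendants(self.graph, term)

    def parent_edges(self, term: str):
        """(parent, relation) pairs for a term's outgoing edges."""
        for _, parent, rel in self.graph.out_edges(term, keys=True):
            yield parent, rel


def annotate_with_ancestors(
    gene_to_terms: dict[str, set[str]],
    ontology: OntologyGraph,
    min_genes: int = 2,
) -> dict[str, set[str]]:
    """Propagate annotations upward, then drop sparsely annotated terms.

    Each gene keeps its direct terms plus every ancestor; terms annotated
    to fewer than ``min_genes`` genes of the input set are removed from all
    genes. Unknown term ids are skipped with a warning.
    """
    import warnings

    expanded: dict[str, set[str]] = {}
    for gene, terms in gene_to_terms.items():
        closure: set[str] = set()
        for t in terms:
            if t not in ontology.graph:
                warnings.warn(f"unknown term {t!r} for gene {gene!r}; skipped",
                              stacklevel=2)
                continue
            closure.add(t)
            closure |= ontology.ancestors(t)
        expanded[gene] = closure
    term_counts: dict[str, int] = {}
    for terms in expanded.values():
        for t in terms:
            term_counts[t] = term_counts.get(t, 0) + 1
    keep = {t for t, c in term_counts.items() if c >= min_genes}
    return {g: terms & keep for g, terms in expanded.items()}


def _semantic_values(term: str, ontology: OntologyGraph,
                     weights: dict[str, float]) -> dict[str, float]:
    """S-value of every ancestor (and the term itself) w.r.t. ``term``.

    S(term) = 1; S(t) = max over edges (c -> t) with c in the induced DAG
    of weight(edge) * S(c). Computed by relaxation over a topological
    order of the induced ancestor DAG.
    """
    nodes = {term} | ontology.ancestors(term)
    sub = ontology.graph.subgraph(nodes)
    s_values = {term: 1.0}
    for node in nx.topological_sort(sub):
        if node not in s_values:
            continue
        base = s_values[node]
        for parent, rel in ontology.parent_edges(node):
            if parent not in nodes:
                continue
            w = weights.get(rel)
            if w is None:
                continue
            cand = base * w
            if cand > s_values.get(parent, 0.0):
                s_values[parent] = cand
    return s_values


def wang_similarity(
    term_a: str,
    term_b: str,
    ontology: OntologyGraph,
    weights: dict[str, float] = DEFAULT_EDGE_WEIGHTS,
) -> float:
    """Wang semantic similarity of two same-namespace terms, in [0, 1]."""
    ns_a = ontology.namespaces.get(term_a)
    ns_b = ontology.namespaces.get(term_b)
    if ns_a != ns_b:
        raise ValueError(f"cross-namespace pair: {term_a} ({ns_a}) vs {term_b} ({ns_b})")
    if term_a == term_b:
        return 1.0
    sa = _semantic_values(term_a, ontology, weights)
    sb = _semantic_values(term_b, ontology, weights)
    common = set(sa) & set(sb)
    num = sum(sa[t] + sb[t] for t in common)
    den = sum(sa.values()) + sum(sb.values())
    return num / den


def similarity_matrix(terms: list[str], ontology: OntologyGraph,
                      weights: dict[str, float] = DEFAULT_EDGE_WEIGHTS) -> pd.DataFrame:
    n = len(terms)
    sim = np.eye(n)
    cache = {t: _semantic_values(t, ontology, weights) for t in terms}
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = cache[terms[i]], cache[terms[j]]
            common = set(sa) & set(sb)
            num = sum(sa[t] + sb[t] for t in common)
            den = sum(sa.values()) + sum(sb.values())
            sim[i, j] = sim[j, i] = num / den
    return pd.DataFrame(sim, index=terms, columns=terms)


def cluster_terms(similarity: pd.DataFrame, k: int = 20) -> pd.Series:
    """Cut an average-linkage tree on distance 1 - similarity into k clusters.

    k is capped at the term count; cluster labels are canonicalized so that
    cluster 1 is the one containing the first term (in index order), etc.
    Returns a Series term -> cluster id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    terms = list(similarity.index)
    k = min(k, len(terms))
    if len(terms) == 1:
        return pd.Series([1], index=terms, name="cluster")
    dist = 1.0 - similarity.to_numpy()
    np.fill_diagonal(dist, 0.0)
    if not np.allclose(dist, dist.T):
        raise ValueError("similarity matrix must be symmetric")
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    # canonical relabeling by order of first appearance
    seen: dict[int, int] = {}
    canon = []
    for lab in labels:
        if lab not in seen:
            seen[lab] = len(seen) + 1
        canon.append(seen[lab])
    return pd.Series(canon, index=terms, name="cluster")


def cluster_contributions(
    clusters: pd.Series,
    annotations: dict[str, set[str]],
    subset: set[str],
) -> pd.DataFrame:
    """Per-cluster percentage of subset genes annotated to a member term."""
    subset_in = [g for g in subset if g in annotations]
    rows = []
    for cid in sorted(clusters.unique()):
        members = set(clusters.index[clusters == cid])
        genes = [g for g in subset_in if annotations[g] & members]
        pct = 100.0 * len(genes) / len(subset_in) if subset_in else 0.0
        rows.append({"cluster": cid, "n_genes": len(genes),
                     "contribution_pct": pct, "genes": sorted(genes)})
    return pd.DataFrame(rows).set_index("cluster")


def fisher_contrast(
    clusters: pd.Series,
    annotations: dict[str, set[str]],
    subset_a: set[str],
    subset_b: set[str],
) -> pd.DataFrame:
    """Two-sided Fisher exact test of subset contributions per cluster.

    The 2x2 table is subset membership x (annotated to cluster vs not).
    """
    if not subset_a or not subset_b:
        raise ValueError("subsets must be non-empty")
    contrib_a = cluster_contributions(clusters, annotations, subset_a)
    contrib_b = cluster_contributions(clusters, annotations, subset_b)
    rows = []
    n_a = len([g for g in subset_a if g in annotations])
    n_b = len([g for g in subset_b if g in annotations])
    for cid in contrib_a.index:
        a_in = int(contrib_a.at[cid, "n_genes"])
        b_in = int(contrib_b.at[cid, "n_genes"])
        table = [[a_in, n_a - a_in], [b_in, n_b - b_in]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"cluster": cid,
                     "contribution_a_pct": contrib_a.at[cid, "contribution_pct"],
                     "contribution_b_pct": contrib_b.at[cid, "contribution_pct"],
                     "a_in": a_in, "b_in": b_in, "p_value": float(p)})
    return pd.DataFrame(rows).set_index("cluster")


def cluster_go_terms(
    ontology: OntologyGraph,
    gene_to_terms: dict[str, set[str]],
    subset_a: set[str],
    subset_b: set[str],
    k: int = 20,
    min_genes: int = 2,
    weights: dict[str, float] = DEFAULT_EDGE_WEIGHTS,
) -> dict[str, dict]:
    """Full per-namespace pipeline: expand, filter, cluster, contrast.

    Returns a mapping namespace -> {"clusters": Series, "contrast": DataFrame}.
    """
    annotations = annotate_with_ancestors(gene_to_terms, ontology, min_genes)
    used_terms = sorted(set().union(*annotations.values()) if annotations else set())
    results: dict[str, dict] = {}
    for ns in sorted({ontology.namespaces.get(t, "") for t in used_terms}):
        ns_terms = [t for t in used_terms if ontology.namespaces.get(t) == ns]
        if not ns_terms:
            continue
        sim = similarity_matrix(ns_terms, ontology, weights)
        clusters = cluster_terms(sim, k=k)
        ns_annotations = {g: terms & set(ns_terms) for g, terms in annotations.items()}
        contrast = fisher_contrast(clusters, ns_annotations, subset_a, subset_b)
        results[ns] = {"clusters": clusters, "contrast": contrast}
    return results
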