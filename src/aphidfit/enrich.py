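"""GO-term over-representation analysis of a gene list against a background.

The test per term is the classical 2×2 contingency approach popularised by
GOstat-style tools: genes in-list vs out-of-list crossed with has-term vs
lacks-term, evaluated by a Pearson chi-square test, falling back to a
two-sided Fisher exact test whenever any expected cell count is below 5.
The two-sided Fisher p is the doubled smaller hypergeometric tail (capped at
1).  BH FDR is computed across tested terms.

Ontology support is limited to ``is_a`` edges: annotations can be propagated
to all ancestors (the true-path rule), and terms carry a *level* — by default
the shortest is_a path length from their namespace root — so results can be
cut at a fixed level (e.g. "level 3 molecular functions").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "Ontology",
    "load_obo",
    "propagate_annotations",
    "term_levels",
    "fisher_two_sided",
    "chi_square_2x2",
    "enrich",
    "level_filter",
]


@dataclass(frozen=True)
class Ontology:
    """A DAG of terms connected by is_a edges (child -> parents)."""

    parents: Mapping[str, frozenset]
    names: Mapping[str, str] = field(default_factory=dict)
    namespaces: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        parents = {t: frozenset(ps) for t, ps in self.parents.items()}
        graph = self._graph(parents)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"is_a cycle detected: {cycle}")
        object.__setattr__(self, "parents", parents)

    @staticmethod
    def _graph(parents: Mapping[str, frozenset]) -> nx.DiGraph:
        g = nx.DiGraph()
        for term, ps in parents.items():
            g.add_node(term)
            for p in ps:
                g.add_edge(term, p)  # edge child -> parent
        return g

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph(self.parents)

    def ancestors(self, term: str) -> frozenset:
        """All terms reachable from ``term`` along is_a edges (excl. itself)."""
        if term not in self.graph:
            return frozenset()
        return frozenset(nx.descendants(self.graph, term))

    def roots(self) -> frozenset:
        g = self.graph
        return frozenset(n for n in g.nodes if g.out_degree(n) == 0)


def load_obo(path) -> Ontology:
    """Read an OBO file, keeping only is_a edges (other relations ignored)."""
    import obonet

    graph = obonet.read_obo(path)
    parents: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        names[node] = data.get("name", node)
        if "namespace" in data:
            namespaces[node] = data["namespace"]
        parents.setdefault(node, set())
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents.setdefault(child, set()).add(parent)
    return Ontology(parents=parents, names=names, namespaces=namespaces)


def propagate_annotations(
    annotations: Mapping[str, Iterable[str]], ontology: Ontology
) -> dict[str, frozenset]:
    """True-path propagation: each gene gains every is_a ancestor of its terms.

    Terms missing from the ontology are kept unpropagated with a warning.
    """
    import warnings

    known = set(ontology.parents)
    anc_cache: dict[str, frozenset] = {}
    out: dict[str, frozenset] = {}
    missing: set[str] = set()
    for gene, terms in annotations.items():
        full: set[str] = set()
        for t in terms:
            full.add(t)
            if t in known:
                if t not in anc_cache:
                    anc_cache[t] = ontology.ancestors(t)
                full |= anc_cache[t]
            else:
                missing.add(t)
        out[gene] = frozenset(full)
    if missing:
        warnings.warn(
            f"{len(missing)} annotation terms missing from the ontology were kept unpropagated",
            stacklevel=2,
        )
    return out


def term_levels(ontology: Ontology, *, mode: str = "shortest") -> dict[str, int]:
    """Level of every term: is_a path length to its namespace root.

    ``mode="shortest"`` (default) uses the shortest path; ``mode="longest"``
    the longest path through the DAG.  A root has level 0, its children 1.
    When a term has a namespace, only roots of the same namespace count.
    """
    if mode not in {"shortest", "longest"}:
        raise ValueError("mode must be 'shortest' or 'longest'")
    g = ontology.graph  # edges child -> parent
    roots = ontology.roots()
    order = list(nx.topological_sort(g))  # children before parents
    best: dict[str, int] = {}
    agg = min if mode == "shortest" else max
    for node in reversed(order):  # parents first
        if node in roots:
            best[node] = 0
            continue
        cand = [best[p] + 1 for p in g.successors(node) if p in best]
        if cand:
            best[node] = agg(cand)
    ns = ontology.namespaces
    if ns:
        # recompute restricted to same-namespace roots where namespace is known
        best_ns: dict[str, int] = {}
        for node in reversed(order):
            if node in roots:
                best_ns[node] = 0
                continue
            node_ns = ns.get(node)
            cand = [
                best_ns[p] + 1
                for p in g.successors(node)
                if p in best_ns and (node_ns is None or ns.get(p) == node_ns)
            ]
            if cand:
                best_ns[node] = agg(cand)
        best = best_ns
    return best


def fisher_two_sided(k: int, K: int, n: int, N: int) -> float:
    """Two-sided Fisher exact p by doubling the smaller hypergeometric tail.

    ``k`` genes of the ``n``-gene list carry the term; ``K`` of the ``N``-gene
    background do.  p = min(1, 2·min(P(X ≤ k), P(X ≥ k))) for
    X ~ Hypergeom(N, K, n).
    """
    lower = stats.hypergeom.cdf(k, N, K, n)
    upper = stats.hypergeom.sf(k - 1, N, K, n)
    return float(min(1.0, 2.0 * min(lower, upper)))


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2×2 table."""
    table = np.asarray(table, dtype=float)
    expected = stats.contingency.expected_freq(table)
    statistic = float(((table - expected) ** 2 / expected).sum())
    return statistic, float(stats.chi2.sf(statistic, 1))


def enrich(
    gene_list: Iterable[str],
    background: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    *,
    min_count: int = 3,
    term_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-term over-representation table for a gene list vs its background.

    For each term with at least ``min_count`` background genes, the 2×2 table
    (in-list/out-list × has-term/lacks-term) is tested by chi-square, or by
    the two-sided Fisher exact test when any expected cell is below 5; BH FDR
    runs across tested terms.  Direction is reported as "over"/"under" from
    k versus the expected count n·K/N.
    """
    genes = set(gene_list)
    universe = set(background)
    if not genes or not universe:
        raise ValueError("gene list and background must be non-empty")
    offenders = genes - universe
    if offenders:
        raise ValueError(
            f"gene list not contained in background; offenders include "
            f"{sorted(offenders)[:10]}"
        )
    N = len(universe)
    n = len(genes)
    term_to_background: dict[str, int] = {}
    term_to_hits: dict[str, int] = {}
    for gene in universe:
        for term in annotations.get(gene, ()):
            term_to_background[term] = term_to_background.get(term, 0) + 1
            if gene in genes:
                term_to_hits[term] = term_to_hits.get(term, 0) + 1
    rows = []
    for term, K in sorted(term_to_background.items()):
        if K < min_count:
            continue
        k = term_to_hits.get(term, 0)
        table = np.array([[k, n - k], [K - k, N - n - (K - k)]], dtype=float)
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            p = fisher_two_sided(k, K, n, N)
            statistic = math.nan
            test_used = "fisher"
        else:
            statistic, p = chi_square_2x2(table)
            test_used = "chi-square"
        exp_k = n * K / N
        rows.append(
            {
                "term": term,
                "name": (term_names or {}).get(term, ""),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "expected": exp_k,
                "statistic": statistic,
                "test": test_used,
                "direction": "over" if k > exp_k else ("under" if k < exp_k else "equal"),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    return out


def level_filter(
    rows: pd.DataFrame, levels: Mapping[str, int], level: int
) -> pd.DataFrame:
    """Keep enrichment rows whose term sits at exactly the requested level."""
    if rows.empty:
        return rows
    keep = rows["term"].map(lambda t: levels.get(t) == level)
    return rows[keep].reset_index(drop=True)
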