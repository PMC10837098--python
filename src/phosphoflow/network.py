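"""PPI network merging, degree centrality, hubs, and enrichment tests.

The merged experimental interactome is an undirected simple graph whose
edges remember which source list(s) contributed them.  Hubs are defined
by a top-fraction degree cutoff (default ~top 5%, ties included, hence
"approximately").  Enrichment of a node category among hubs is tested
with one-sided hypergeometric tails; the degree shift between category
and non-category nodes with a two-sample t-test (Welch by default).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CATEGORIES = ("phospho", "immune", "g_interactome", "effector")


class NetworkFormatError(ValueError):
    pass


@dataclass
class HubDefinition:
    top_fraction: float
    degree_cutoff: int
    achieved_fraction: float


@dataclass
class EnrichmentResult:
    """2x2 hub-by-category counts with one-sided hypergeometric tails."""

    scope: str
    category: str
    population_size: int
    n_hubs: int
    n_in_category: int
    n_hub_in_category: int
    p_over: float
    p_under: float
    fold_enrichment: float | None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        return d


# ----------------------------------------------------------------------

def build_ppie(edge_files, category_files=None) -> nx.Graph:
    """Merge edge lists into one simple undirected graph with provenance.

    ``edge_files``: 2- or 3-column (node_a, node_b[, source]) TSVs, header
    optional on the source column only if named; files without a source
    column contribute their file stem as source name.  Self-loops are
    dropped (and counted); duplicate unordered pairs are merged, pooling
    their sources.  ``category_files`` maps a category name to a
    one-column TSV of locus codes.  Locus codes are upper-cased.
    """
    g = nx.Graph()
    n_loops = 0
    for path in edge_files:
        path = Path(path)
        default_source = path.stem
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if lineno == 1 and parts[0].strip().lower() in {"node_a", "source", "from", "protein_a"}:
                    continue
                if len(parts) < 2:
                    raise NetworkFormatError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
                a, b = parts[0].strip().upper(), parts[1].strip().upper()
                if not a or not b:
                    raise NetworkFormatError(f"{path}:{lineno}: empty node name")
                source = parts[2].strip() if len(parts) > 2 and parts[2].strip() else default_source
                if a == b:
                    n_loops += 1
                    continue
                if g.has_edge(a, b):
                    g.edges[a, b]["sources"] = g.edges[a, b]["sources"] | {source}
                else:
                    g.add_edge(a, b, sources=frozenset({source}))
    if n_loops:
        log.info("dropped %d self-loop(s) while merging", n_loops)
    for node in g.nodes:
        for cat in CATEGORIES:
            g.nodes[node].setdefault(cat, False)
    if category_files:
        for cat, path in category_files.items():
            loci = _read_node_list(path)
            hit = 0
            for locus in loci:
                if locus in g:
                    g.nodes[locus][cat] = True
                    hit += 1
            log.info("category %s: %d/%d listed loci present in network", cat, hit, len(loci))
    return g


def _read_node_list(path) -> set[str]:
    out = set()
    with open(path) as fh:
        for line in fh:
            tok = line.strip().split("\t")[0].strip().upper()
            if tok and tok.lower() not in {"locus", "node", "gene"}:
                out.add(tok)
    return out


def annotate_categories(g: nx.Graph, category_nodes: dict[str, set[str]]) -> None:
    """Set boolean category flags from in-memory node sets."""
    for node in g.nodes:
        for cat in CATEGORIES:
            g.nodes[node].setdefault(cat, False)
    for cat, loci in category_nodes.items():
        upper = {str(x).upper() for x in loci}
        for node in g.nodes:
            if str(node).upper() in upper:
                g.nodes[node][cat] = True


def degree_centrality(g: nx.Graph) -> dict[str, int]:
    """Integer degree (number of distinct neighbors) per node."""
    return {v: int(d) for v, d in g.degree()}


def category_nodes(g: nx.Graph, category: str) -> set[str]:
    return {v for v, d in g.nodes(data=True) if d.get(category, False)}


# ----------------------------------------------------------------------

def hub_cutoff(degrees: dict[str, int], top_fraction: float = 0.05) -> HubDefinition:
    """Smallest degree cutoff keeping at most ``top_fraction`` of nodes.

    All nodes at the cutoff degree count as hubs (ties included), which is
    why the achieved fraction is only approximately the requested one.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    if not degrees:
        raise ValueError("empty degree map")
    vals = np.asarray(sorted(degrees.values()))
    n = vals.size
    # candidate cutoffs: each distinct degree and one past the maximum
    candidates = np.unique(vals).tolist() + [int(vals.max()) + 1]
    best = candidates[-1]
    for c in sorted(candidates):
        frac = float((vals >= c).sum()) / n
        if frac <= top_fraction:
            best = int(c)
            break
    achieved = float((vals >= best).sum()) / n
    return HubDefinition(top_fraction=top_fraction, degree_cutoff=best, achieved_fraction=achieved)


def hub_nodes(degrees: dict[str, int], definition: HubDefinition) -> set[str]:
    return {v for v, d in degrees.items() if d >= definition.degree_cutoff}


def hub_enrichment(
    g: nx.Graph,
    hubs: set[str],
    category: str,
    scope: set[str] | None = None,
    scope_name: str = "PPIE",
) -> EnrichmentResult:
    """One-sided hypergeometric test of category membership among hubs.

    Population N = nodes in scope, successes K = hubs in scope, draws
    n = category nodes in scope, observed x = category hubs in scope.
    """
    nodes = set(g.nodes) if scope is None else (set(scope) & set(g.nodes))
    if not nodes:
        raise ValueError("empty scope for enrichment test")
    if not hubs <= set(g.nodes):
        raise ValueError("hubs must be a subset of the graph's nodes")
    cat = category_nodes(g, category) & nodes
    hub_in_scope = hubs & nodes
    x = len(cat & hub_in_scope)
    big_n, big_k, n = len(nodes), len(hub_in_scope), len(cat)
    rv = stats.hypergeom(M=big_n, n=big_k, N=n)
    p_over = float(rv.sf(x - 1))
    p_under = float(rv.cdf(x))
    fold = None
    if n > 0 and big_k > 0:
        fold = (x / n) / (big_k / big_n)
    return EnrichmentResult(
        scope=scope_name, category=category, population_size=big_n, n_hubs=big_k,
        n_in_category=n, n_hub_in_category=x,
        p_over=min(max(p_over, np.finfo(float).tiny), 1.0),
        p_under=min(max(p_under, np.finfo(float).tiny), 1.0),
        fold_enrichment=fold,
    )


def degree_shift_test(
    g: nx.Graph,
    category: str,
    method: str = "welch",
    log_degrees: bool = False,
) -> tuple[float, float, tuple[float, float]]:
    """Compare degrees of category vs non-category nodes.

    ``method``: "welch" (default), "student" (pooled variance) or
    "mannwhitney".  Returns (statistic, p_value, (mean_cat, mean_rest)).
    """
    degs = degree_centrality(g)
    cat = category_nodes(g, category)
    a = np.array([degs[v] for v in g.nodes if v in cat], dtype=float)
    b = np.array([degs[v] for v in g.nodes if v not in cat], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 nodes for the degree test")
    if log_degrees:
        a = np.log1p(a)
        b = np.log1p(b)
    means = (float(a.mean()), float(b.mean()))
    if method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue), means
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if means[0] == means[1]:
            return 0.0, 1.0, means
        warnings.warn("degenerate zero within-group variance in degree test", stacklevel=2)
        return float("inf"), float(np.finfo(float).tiny), means
    res = stats.ttest_ind(a, b, equal_var=(method == "student"))
    return float(res.statistic), float(res.pvalue), means


# ----------------------------------------------------------------------

def node_table(g: nx.Graph, hubs: set[str]) -> pd.DataFrame:
    degs = degree_centrality(g)
    rows = [
        {"locus": v, "degree": degs[v], "is_hub": v in hubs,
         **{cat: bool(g.nodes[v].get(cat, False)) for cat in CATEGORIES}}
        for v in sorted(g.nodes)
    ]
    return pd.DataFrame(rows)


def write_sif(g: nx.Graph, path, relation: str = "pp") -> None:
    """Cytoscape-loadable SIF export (one ``a pp b`` line per edge)."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
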