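"""Co-expression network filtering, hubs, enrichment, target screen.

The co-expression network arrives as an undirected weighted edge list
(weights in [0, 1], e.g. topological-overlap weights from an external
tool).  Edges are kept only when strictly heavier than the threshold
(default 0.2); a module's hub is the member with the largest sum of
incident intra-module edge weights.  Module detection itself is out of
scope: when no external module assignment is supplied, connected
components of the filtered network serve as a clearly labelled stand-in.

The final *target-gene screen* intersects, per variety, three evidence
sets: drought-induced genes, genes of the drought-associated module, and
genes near drought-changed (dg / dl) TAD boundaries; targets of the two
varieties are then compared for shared and variety-specific genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import InputError

DEFAULT_EDGE_THRESHOLD = 0.2


def filter_edges(
    edges: pd.DataFrame, threshold: float = DEFAULT_EDGE_THRESHOLD
) -> nx.Graph:
    """Keep edges with weight strictly greater than ``threshold``.

    ``edges`` has columns gene_a / gene_b / weight.  Self-edges are
    rejected, weights must lie in [0, 1], and nodes isolated after the
    filter are dropped.  Node and edge counts are stored on
    ``graph.graph``.
    """
    req = {"gene_a", "gene_b", "weight"}
    if not req <= set(edges.columns):
        raise InputError(f"edge list needs columns {sorted(req)}")
    w = pd.to_numeric(edges["weight"], errors="coerce")
    if w.isna().any() or (w < 0).any() or (w > 1).any():
        raise InputError("edge weights must be numbers in [0, 1]")
    if (edges["gene_a"] == edges["gene_b"]).any():
        raise InputError("self-edges are not allowed")
    kept = edges[w > threshold]
    g = nx.Graph()
    for a, b, wt in kept[["gene_a", "gene_b", "weight"]].itertuples(
            index=False):
        g.add_edge(a, b, weight=float(wt))
    g.graph["threshold"] = threshold
    g.graph["n_nodes"] = g.number_of_nodes()
    g.graph["n_edges"] = g.number_of_edges()
    return g


def fallback_modules(graph: nx.Graph) -> pd.Series:
    """Connected components as module labels (synthetic stand-in).

    Labelled ``CC1``, ``CC2``, ... by decreasing size; a stand-in for an
    external co-expression module assignment, suitable only for fully
    synthetic runs.
    """
    comps = sorted(nx.connected_components(graph),
                   key=lambda c: (-len(c), min(c)))
    lab = {}
    for k, comp in enumerate(comps, start=1):
        for gmember in comp:
            lab[gmember] = f"CC{k}"
    return pd.Series(lab, name="module")


def find_hubs(
    graph: nx.Graph, modules: pd.Series, k: int = 1
) -> dict[str, list[str]]:
    """Top-``k`` hub genes per module by intra-module weight sum.

    Every node must carry a module label.  Ties break lexicographically
    by gene id.  Asking for more hubs than a module holds returns the
    whole module with a warning.
    """
    unlabeled = [n for n in graph.nodes if n not in modules.index]
    if unlabeled:
        raise InputError(f"nodes without module label: {sorted(unlabeled)[:5]}")
    hubs: dict[str, list[str]] = {}
    for mod in sorted(modules.loc[list(graph.nodes)].unique()):
        members = [n for n in graph.nodes if modules[n] == mod]
        strength = {
            n: sum(d["weight"] for nb, d in graph[n].items()
                   if modules.get(nb) == mod)
            for n in members
        }
        ranked = sorted(members, key=lambda n: (-strength[n], n))
        if k > len(ranked):
            warnings.warn(
                f"module {mod} has only {len(ranked)} genes; returning all",
                stacklevel=2,
            )
        hubs[mod] = ranked[:k]
    return hubs


def module_expression_profile(
    module_genes, expr: pd.DataFrame
) -> pd.Series:
    """Mean per-gene z-score profile of a module across samples.

    Each gene is z-scored across samples, then averaged over module
    genes per sample.  Genes with zero variance are masked out (they
    carry no profile information); genes absent from the matrix are
    ignored, but an empty intersection is an error.
    """
    present = [gene for gene in module_genes if gene in expr.index]
    if not present:
        raise InputError("no module gene present in the expression matrix")
    x = expr.loc[present].to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.any():
        return pd.Series(0.0, index=expr.columns)
    z = (x[keep] - mu[keep]) / sd[keep]
    return pd.Series(z.mean(axis=0), index=expr.columns)


# ---------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    overlap: int
    set_size: int
    term_size: int
    universe_size: int
    odds_ratio: float
    p: float
    padj: float


def fisher_enrichment(
    gene_set: set[str],
    universe: set[str],
    terms: dict[str, set[str]],
) -> list[EnrichmentResult]:
    """One-sided Fisher exact enrichment of a gene set against term sets.

    Terms are restricted to the universe; the gene set must be contained
    in it.  BH correction is applied across terms.  Results are sorted
    by adjusted then raw p.
    """
    if not gene_set <= universe:
        raise InputError("gene set must be a subset of the universe")
    names = sorted(terms)
    raw = []
    rows = []
    for t in names:
        tg = terms[t] & universe
        a = len(gene_set & tg)
        b = len(gene_set) - a
        c = len(tg) - a
        d = len(universe) - len(gene_set) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        raw.append(p)
        rows.append((t, a, len(gene_set), len(tg), len(universe), odds))
    padj = multipletests(raw, method="fdr_bh")[1] if raw else []
    out = [
        EnrichmentResult(term=t, overlap=a, set_size=s, term_size=ts,
                         universe_size=u, odds_ratio=float(o),
                         p=float(p), padj=float(q))
        for (t, a, s, ts, u, o), p, q in zip(rows, raw, padj)
    ]
    return sorted(out, key=lambda r: (r.padj, r.p, r.term))


# ---------------------------------------------------------------------
# target-gene screen
# ---------------------------------------------------------------------

@dataclass
class TargetGeneReport:
    targets: dict[str, set[str]]
    shared: set[str]
    specific: dict[str, set[str]]
    #: per variety, per gene: which of the three evidence flags it carries
    evidence: dict[str, pd.DataFrame] = field(default_factory=dict)


def screen_target_genes(
    evidence_by_variety: dict[str, dict[str, set[str]]],
) -> TargetGeneReport:
    """Three-evidence intersection per variety, then cross-variety overlap.

    ``evidence_by_variety`` maps each variety to its three evidence sets
    under the keys ``induced``, ``module`` and ``tad_change``.  The
    target set of a variety is the intersection of its three sets; the
    shared set is the intersection of all per-variety target sets and
    specific sets are their complements within each variety.
    """
    targets: dict[str, set[str]] = {}
    evidence_tables: dict[str, pd.DataFrame] = {}
    for variety, ev in evidence_by_variety.items():
        missing = {"induced", "module", "tad_change"} - set(ev)
        if missing:
            raise InputError(
                f"variety {variety!r} lacks evidence set(s) {sorted(missing)}"
            )
        for name, s in ev.items():
            if not s:
                warnings.warn(
                    f"evidence set {name!r} for {variety!r} is empty",
                    stacklevel=2,
                )
        targets[variety] = ev["induced"] & ev["module"] & ev["tad_change"]
        genes = sorted(ev["induced"] | ev["module"] | ev["tad_change"])
        evidence_tables[variety] = pd.DataFrame({
            "gene": genes,
            "induced": [gene in ev["induced"] for gene in genes],
            "module": [gene in ev["module"] for gene in genes],
            "tad_change": [gene in ev["tad_change"] for gene in genes],
        })
    shared = set.intersection(*targets.values()) if targets else set()
    specific = {v: t - shared for v, t in targets.items()}
    return TargetGeneReport(targets=targets, shared=shared,
                            specific=specific, evidence=evidence_tables)
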