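"""Chemical-similarity metabolic networks and pathway analysis.

Edges connect metabolite pairs whose binary-fingerprint Tanimoto similarity
reaches a cutoff (0.7 by default) and/or pairs standing in a
substrate-product (reaction-pair) relation; the network exports to SIF with
a node-attribute sidecar for Cytoscape-style tools. Pathway
over-representation uses the upper-tail hypergeometric test and pathway
impact is the hit share of relative-betweenness centrality, with pathway
graphs built from reaction pairs restricted to pathway members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from csfmet.datatypes import ValidationError
from csfmet.univariate import ContrastResult

logger = logging.getLogger(__name__)


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto similarity |A & B| / |A | B| of two binary fingerprints.

    Undefined (raises) when both fingerprints are all-zero.
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("fingerprints have different lengths")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        raise ValidationError("Tanimoto undefined: both fingerprints empty")
    return int(np.logical_and(a, b).sum()) / union


@dataclass
class MetabolicNetwork:
    """Typed metabolite graph: tanimoto / rpair / both edges, node stats."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    cutoff: float = 0.7

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": min(u, v), "target": max(u, v), **d}
            for u, v, d in self.graph.edges(data=True)
        ]
        return (
            pd.DataFrame(rows, columns=["source", "target", "type", "similarity"])
            .sort_values(["source", "target"])
            .reset_index(drop=True)
        )


def build_network(
    metabolites: pd.DataFrame,
    cutoff: float = 0.7,
    rpairs=(),
) -> MetabolicNetwork:
    """All-pairs Tanimoto network with reaction-pair overlay.

    Every metabolite with a fingerprint is compared against every other; a
    similarity edge is added at ``similarity >= cutoff``. Reaction pairs are
    added regardless of similarity; a pair satisfying both criteria is typed
    ``both``. Pairs whose Tanimoto is undefined (two empty fingerprints) are
    skipped; reaction pairs naming unknown metabolites are skipped with a
    warning. All metabolites appear as nodes.
    """
    g = nx.Graph()
    ids = list(metabolites.index)
    g.add_nodes_from(ids)
    fps = {}
    if "fingerprint" in metabolites.columns:
        for mid, fp in metabolites["fingerprint"].items():
            if fp is not None and not (np.isscalar(fp) and pd.isna(fp)):
                fps[mid] = np.asarray(fp, dtype=bool)
    known = set(ids)
    for i, a in enumerate(ids):
        if a not in fps:
            continue
        for b in ids[i + 1:]:
            if b not in fps:
                continue
            union = int((fps[a] | fps[b]).sum())
            if union == 0:
                continue  # undefined pair, reported as missing
            sim = int((fps[a] & fps[b]).sum()) / union
            if sim >= cutoff:
                g.add_edge(a, b, type="tanimoto", similarity=sim)
    for a, b in rpairs:
        if a not in known or b not in known:
            logger.warning("reaction pair (%s, %s) references unknown metabolite", a, b)
            continue
        if a == b:
            continue
        if g.has_edge(a, b):
            g.edges[a, b]["type"] = (
                "both" if g.edges[a, b]["type"] in ("tanimoto", "both") else "rpair"
            )
        else:
            g.add_edge(a, b, type="rpair", similarity=np.nan)
    return MetabolicNetwork(graph=g, cutoff=cutoff)


def annotate_nodes(
    net: MetabolicNetwork, contrast: ContrastResult, alpha: float = 0.05
) -> MetabolicNetwork:
    """Attach contrast statistics to nodes.

    Significant nodes get direction up/down and size |log2 fold-change| (so
    halving and doubling are symmetric); non-significant nodes are marked
    ``ns`` and kept in the data model, flagged for display filtering.
    """
    t = contrast.table
    for node in net.graph.nodes:
        if node not in t.index:
            continue
        row = t.loc[node]
        fc = row["fold_change"]
        sig = bool(row["significant"]) and row["testable"] and fc != 1.0
        net.graph.nodes[node].update(
            fold_change=fc if row["testable"] else np.nan,
            significant=sig,
            direction=("up" if fc > 1 else "down") if sig else "ns",
            size=abs(np.log2(fc)) if (row["testable"] and fc > 0) else np.nan,
        )
    return net


def export_sif(net: MetabolicNetwork, path) -> tuple[Path, Path]:
    """Write the edge list as SIF plus a node-attribute TSV sidecar.

    One line per edge, ``source <type> target``, lexicographically ordered;
    attributes cover node, fold_change, direction, significant.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    et = net.edge_table()
    with open(path, "w", encoding="utf-8") as fh:
        for _, row in et.iterrows():
            fh.write(f"{row['source']}\t{row['type']}\t{row['target']}\n")
    attr_path = path.with_suffix(".attrs.tsv")
    rows = []
    for node in sorted(net.graph.nodes):
        d = net.graph.nodes[node]
        rows.append(
            {
                "node": node,
                "fold_change": d.get("fold_change", np.nan),
                "direction": d.get("direction", "ns"),
                "significant": d.get("significant", False),
            }
        )
    pd.DataFrame(rows).to_csv(attr_path, sep="\t", index=False)
    return path, attr_path


def read_sif(path) -> nx.Graph:
    """Re-import an exported SIF edge list."""
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 3:
                s, t, o = parts[0], parts[1], parts[2]
                g.add_edge(s, o, type=t)
    return g


def hypergeom_enrich(hits, pathway, universe) -> float:
    """Upper-tail hypergeometric over-representation p-value.

    P(X >= k) for X ~ Hypergeom(N=|universe|, K=|pathway|, n=|hits|) with
    k = |hits & pathway|.
    """
    hits, pathway, universe = set(hits), set(pathway), set(universe)
    if not universe:
        raise ValidationError("empty universe")
    if not pathway <= universe or not hits <= universe:
        raise ValidationError("hits and pathway must be subsets of the universe")
    k = len(hits & pathway)
    return float(hypergeom.sf(k - 1, len(universe), len(pathway), len(hits)))


def betweenness(graph: nx.Graph) -> dict[str, float]:
    """Relative betweenness centrality: fraction of shortest paths between
    other node pairs passing through each node, normalised by
    (n-1)(n-2)/2. All zeros for n < 3."""
    n = graph.number_of_nodes()
    if n < 3:
        return {v: 0.0 for v in graph.nodes}
    return nx.betweenness_centrality(graph, normalized=True)


def pathway_graph(members, rpairs) -> nx.Graph:
    """Pathway topology: reaction-pair edges restricted to member nodes."""
    g = nx.Graph()
    members = set(members)
    g.add_nodes_from(sorted(members))
    for a, b in rpairs:
        if a in members and b in members and a != b:
            g.add_edge(a, b)
    return g


def pathway_impact(hits, graph: nx.Graph) -> float:
    """Impact = centrality share of the hit metabolites, in [0, 1].

    Sum of relative-betweenness centrality over hits divided by the sum over
    all pathway nodes; 0 when the denominator is 0.
    """
    hits = set(hits)
    if not hits <= set(graph.nodes):
        raise ValidationError("hits must be pathway members")
    c = betweenness(graph)
    total = sum(c.values())
    if total == 0:
        return 0.0
    return sum(c[h] for h in hits) / total


@dataclass
class PathwayEnrichment:
    """Per-pathway over-representation result with impact."""

    pathway: str
    n_universe: int
    n_pathway: int
    n_hits_universe: int
    n_hits_pathway: int
    p_hyper: float
    impact: float


def enrich_pathways(
    hits, metabolites: pd.DataFrame, rpairs=(), adjust: bool = False
) -> pd.DataFrame:
    """Over-representation + impact for every pathway in the annotation.

    The universe is every annotated metabolite; pathway membership comes
    from the ``pathways`` column. Benjamini-Hochberg adjustment across
    pathways is available but off by default.
    """
    universe = set(metabolites.index)
    hits = set(hits) & universe
    pathways: dict[str, set] = {}
    for mid, pws in metabolites["pathways"].items():
        if pws is None or (np.isscalar(pws) and pd.isna(pws)):
            continue
        for pw in pws:
            pathways.setdefault(pw, set()).add(mid)
    rows = []
    for pw in sorted(pathways):
        members = pathways[pw]
        g = pathway_graph(members, rpairs)
        rows.append(
            PathwayEnrichment(
                pathway=pw,
                n_universe=len(universe),
                n_pathway=len(members),
                n_hits_universe=len(hits),
                n_hits_pathway=len(hits & members),
                p_hyper=hypergeom_enrich(hits, members, universe),
                impact=pathway_impact(hits & members, g),
            ).__dict__
        )
    table = pd.DataFrame(rows).set_index("pathway")
    if adjust and len(table):
        from csfmet.univariate import _bh_adjust

        table["p_adjusted"] = _bh_adjust(table["p_hyper"].to_numpy())
    return table
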