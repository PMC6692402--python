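"""Promoter-promoter interaction networks from chromatin loops.

Genes are nodes; an edge joins two genes when some loop has one anchor
overlapping the first gene's promoter and its other anchor overlapping
the second gene's promoter. Multiple loops between the same gene pair
collapse into one edge that keeps the supporting loop ids and their
summed PET count. Degree counts distinct interacting gene partners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, GeneTable, LoopSet, build_trees, overlapping


@dataclass
class GeneNetwork:
    graph: nx.Graph
    report: dict = field(default_factory=dict)

    @property
    def degrees(self) -> pd.Series:
        return pd.Series(dict(self.graph.degree), dtype=int)

    def edge_table(self) -> pd.DataFrame:
        rows = [(u, v, ",".join(sorted(d["loop_ids"])), d["pet_count"],
                 "intra" if d["intra"] else "inter")
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["gene_i", "gene_j", "loop_ids",
                                           "pet_count", "span_type"])


def build_gene_network(loops: LoopSet, genes: GeneTable,
                       promoter_window: int = 2000) -> GeneNetwork:
    """Connect genes whose promoters sit on the two anchors of a loop.

    An anchor covering k promoters fans out to all k genes. Loops that
    touch fewer than two distinct promoters contribute no edge; loops
    whose two anchors hit only one gene are counted as self-loop events.
    """
    prom = genes.promoters(promoter_window)
    trees = build_trees(prom)
    G = nx.Graph()
    n_no_promoter, n_self = 0, 0
    for row in loops.df.itertuples(index=False):
        g1 = {prom["gene_id"].iloc[i] for i in
              overlapping(trees, row.chrom1, row.start1, row.end1)}
        g2 = {prom["gene_id"].iloc[i] for i in
              overlapping(trees, row.chrom2, row.start2, row.end2)}
        if not g1 or not g2:
            n_no_promoter += 1
            continue
        intra = row.chrom1 == row.chrom2
        made_edge = False
        for a in g1:
            for b in g2:
                if a == b:
                    continue
                made_edge = True
                if G.has_edge(a, b):
                    d = G[a][b]
                    d["loop_ids"].add(row.id)
                    d["pet_count"] += row.pet_count
                    d["intra"] = d["intra"] and intra
                else:
                    G.add_edge(a, b, loop_ids={row.id},
                               pet_count=int(row.pet_count), intra=intra)
        if not made_edge:
            n_self += 1
    report = dict(n_loops=len(loops.df), n_without_two_promoters=n_no_promoter,
                  n_self_loop_events=n_self, n_nodes=G.number_of_nodes(),
                  n_edges=G.number_of_edges())
    return GeneNetwork(G, report)


def extract_subnetworks(net: GeneNetwork, min_intra_pets: int = 4,
                        min_inter_pets: int = 6, top_k: int = 100) -> list:
    """Top connected components after PET-support edge filtering.

    Intrachromosomal edges need summed PET count >= ``min_intra_pets``,
    interchromosomal edges >= ``min_inter_pets``. Components are ranked
    by node count, then edge count, then smallest gene id; the ``top_k``
    largest are returned as sorted node lists.
    """
    if min_intra_pets < 1 or min_inter_pets < 1:
        raise ValueError("PET thresholds must be >= 1")
    H = nx.Graph()
    for u, v, d in net.graph.edges(data=True):
        need = min_intra_pets if d["intra"] else min_inter_pets
        if d["pet_count"] >= need:
            H.add_edge(u, v, **d)
    comps = [sorted(c) for c in nx.connected_components(H)]
    comps.sort(key=lambda c: (-len(c), -H.subgraph(c).number_of_edges(), c[0]))
    return comps[:top_k]


def degree_expression_table(net: GeneNetwork, expr: ExpressionMatrix,
                            tissue: str,
                            degree_classes: tuple = (1, 2, 3, 4)) -> pd.DataFrame:
    """Bucket genes by network degree against FPKM in one tissue.

    Degree classes default to 1, 2, 3 and >=4. Returns per-gene rows
    (gene_id, degree, degree_class, fpkm); a Spearman trend over
    (degree, fpkm) is attached as ``.attrs['trend']`` when at least two
    distinct degrees are present. Degree-0 genes (absent from the
    network) are excluded and counted in ``.attrs['n_degree0']``.
    """
    if tissue not in expr.df.columns:
        raise KeyError(f"unknown tissue {tissue!r}")
    deg = net.degrees
    genes = [g for g in deg.index if g in expr.df.index]
    n_deg0 = int(len(expr.df.index.difference(deg.index)))
    rows = []
    top = degree_classes[-1]
    for g in genes:
        d = int(deg[g])
        cls = f">={top}" if d >= top else str(d)
        rows.append((g, d, cls, float(expr.df.loc[g, tissue])))
    out = pd.DataFrame(rows, columns=["gene_id", "degree", "degree_class", "fpkm"])
    out.attrs["n_degree0"] = n_deg0
    if len(out) and out["degree"].nunique() > 1:
        rho, p = stats.spearmanr(out["degree"], out["fpkm"])
        out.attrs["trend"] = dict(spearman_rho=float(rho), p_value=float(p))
    else:
        out.attrs["trend"] = None
    return out
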