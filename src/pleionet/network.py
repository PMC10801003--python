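"""Inter-QTL LD statistic, node merging, and the genetic association network.

Two QTL intervals on the same chromosome are scored by

    Inter-LD = 1/2 * ( aveLD(Q1,Q2) / PmaxLD(Q1) + aveLD(Q1,Q2) / PmaxLD(Q2) )

where aveLD is the mean r2 over all cross pairs (one marker from each
interval) and PmaxLD(Q) is the maximum pairwise r2 within Q (1 for a
single-marker interval). All genotyped markers inside an interval enter
the computation, not only clump members. The statistic is symmetric; it
may exceed 1 when the cross-interval LD average beats both within-interval
maxima, in which case a warning is logged and no cap is applied.

QTL regions from different traits that share >= 1 bp on a chromosome are
merged transitively (union-find) into network nodes. The network then has
trait nodes, merged QTL nodes, trait-association edges, and inter-LD edges
between same-chromosome node pairs at or above a threshold (default 0.4).
Nodes are classed as hub (>= 3 directly associated traits), two-trait,
linked-1-trait (one trait but at least one inter-LD edge), or independent.
Inter-LD edges never add traits to a node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .clumping import pairwise_r2
from .datatypes import GenotypeMatrix, InterLDResult, QTLRegion

logger = logging.getLogger(__name__)

NODE_CLASSES = ("independent", "linked-1-trait", "two-trait", "hub")


@dataclass
class QTLNode:
    """A merged, possibly multi-trait QTL node of the association network."""

    id: str
    chrom: str
    start: int
    end: int
    traits: frozenset[str]
    qtls: list[QTLRegion] = field(default_factory=list)
    min_p: float = float("nan")


def inter_ld(geno: GenotypeMatrix, q1: QTLRegion | QTLNode, q2: QTLRegion | QTLNode) -> InterLDResult | None:
    """Inter-LD between two same-chromosome intervals.

    Returns None (with a warning) when either interval contains no
    polymorphic marker. Missing pairwise r2 values are excluded from the
    cross-pair mean.
    """
    if q1.chrom != q2.chrom:
        raise ValueError(f"inter_ld requires same-chromosome intervals ({q1.chrom} vs {q2.chrom})")
    # canonical order makes the statistic exactly symmetric (the mean over
    # cross pairs is otherwise summed in a different order)
    if (q2.start, q2.end, str(q2.id)) < (q1.start, q1.end, str(q1.id)):
        res = inter_ld(geno, q2, q1)
        if res is None:
            return None
        return InterLDResult(qtl1=q1.id, qtl2=q2.id, ave_ld=res.ave_ld,
                             pmax_ld1=res.pmax_ld2, pmax_ld2=res.pmax_ld1,
                             inter_ld=res.inter_ld)
    idx1 = geno.markers_in_interval(q1.chrom, q1.start, q1.end)
    idx2 = geno.markers_in_interval(q2.chrom, q2.start, q2.end)

    def _pmax(idx: np.ndarray) -> float:
        if len(idx) < 2:
            return 1.0
        r2 = pairwise_r2(geno, idx, idx)
        iu = np.triu_indices(len(idx), k=1)
        vals = r2[iu]
        return float(np.nanmax(vals)) if np.isfinite(vals).any() else float("nan")

    if len(idx1) == 0 or len(idx2) == 0:
        logger.warning("inter_ld: empty interval (%s or %s); pair skipped", q1.id, q2.id)
        return None
    cross = pairwise_r2(geno, idx1, idx2)
    if not np.isfinite(cross).any():
        logger.warning("inter_ld: no polymorphic marker pair between %s and %s; pair skipped",
                       q1.id, q2.id)
        return None
    ave = float(np.nanmean(cross))
    p1, p2 = _pmax(idx1), _pmax(idx2)
    if not (np.isfinite(p1) and np.isfinite(p2)) or p1 == 0 or p2 == 0:
        logger.warning("inter_ld: undefined within-interval LD for %s/%s; pair skipped",
                       q1.id, q2.id)
        return None
    stat = 0.5 * (ave / p1 + ave / p2)
    if stat > 1.0 + 1e-12:
        logger.warning("inter_ld(%s, %s) = %.3f exceeds 1 (cross-LD above both within-QTL maxima)",
                       q1.id, q2.id, stat)
    return InterLDResult(qtl1=q1.id, qtl2=q2.id, ave_ld=ave,
                         pmax_ld1=p1, pmax_ld2=p2, inter_ld=float(stat))


def merge_overlapping_qtls(qtls: list[QTLRegion]) -> list[QTLNode]:
    """Transitive union of same-chromosome QTLs sharing >= 1 bp.

    Sorting by start makes the transitive closure a single sweep per
    chromosome: a region joins the open cluster iff it starts at or
    before the cluster's running end.
    """
    nodes: list[QTLNode] = []
    by_chrom: dict[str, list[QTLRegion]] = {}
    for q in qtls:
        by_chrom.setdefault(q.chrom, []).append(q)
    for chrom in sorted(by_chrom):
        regs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cluster: list[QTLRegion] = []
        end = -1
        for r in regs + [None]:  # sentinel flushes the last cluster
            if r is not None and (not cluster or r.start <= end):
                cluster.append(r)
                end = max(end, r.end)
                continue
            if cluster:
                nodes.append(QTLNode(
                    id=f"N{len(nodes) + 1}",
                    chrom=chrom,
                    start=min(c.start for c in cluster),
                    end=max(c.end for c in cluster),
                    traits=frozenset(c.trait for c in cluster),
                    qtls=list(cluster),
                    min_p=min(c.min_p for c in cluster),
                ))
            if r is not None:
                cluster, end = [r], r.end
    return nodes


def build_network(
    nodes: list[QTLNode],
    geno: GenotypeMatrix | None = None,
    threshold: float = 0.4,
) -> nx.Graph:
    """Assemble the trait/QTL association network.

    Adds a trait node per associated trait, an association edge for every
    (QTL node, trait) membership, and — when genotypes are supplied — an
    inter-LD edge for every same-chromosome node pair whose Inter-LD over
    the merged spans reaches ``threshold``. Node classes follow the trait
    count and inter-LD degree; inter-LD edges never change trait sets.
    """
    g = nx.Graph()
    for t in sorted({t for n in nodes for t in n.traits}):
        g.add_node(t, kind="trait")
    for n in nodes:
        g.add_node(n.id, kind="qtl", chrom=n.chrom, start=n.start, end=n.end,
                   traits=",".join(sorted(n.traits)), min_p=n.min_p)
        for t in sorted(n.traits):
            g.add_edge(n.id, t, kind="association", weight=1.0)

    if geno is not None:
        by_chrom: dict[str, list[QTLNode]] = {}
        for n in nodes:
            by_chrom.setdefault(n.chrom, []).append(n)
        for chrom_nodes in by_chrom.values():
            for i in range(len(chrom_nodes)):
                for j in range(i + 1, len(chrom_nodes)):
                    res = inter_ld(geno, chrom_nodes[i], chrom_nodes[j])
                    if res is not None and res.inter_ld >= threshold:
                        g.add_edge(chrom_nodes[i].id, chrom_nodes[j].id,
                                   kind="inter_ld", weight=res.inter_ld)

    for n in nodes:
        k = len(n.traits)
        has_ld = any(d.get("kind") == "inter_ld" for _, _, d in g.edges(n.id, data=True))
        if k >= 3:
            cls = "hub"
        elif k == 2:
            cls = "two-trait"
        elif has_ld:
            cls = "linked-1-trait"
        else:
            cls = "independent"
        g.nodes[n.id]["node_class"] = cls
    return g


def classify_counts(net: nx.Graph) -> dict[str, int]:
    """Node-class bookkeeping over the QTL nodes."""
    counts = {c: 0 for c in NODE_CLASSES}
    for _, d in net.nodes(data=True):
        if d.get("kind") == "qtl":
            counts[d["node_class"]] += 1
    counts["qtl_nodes"] = sum(counts[c] for c in NODE_CLASSES)
    return counts


def node_table(net: nx.Graph) -> pd.DataFrame:
    rows = []
    for nid, d in net.nodes(data=True):
        rows.append({
            "id": nid,
            "kind": d.get("kind", ""),
            "chrom": d.get("chrom", ""),
            "start": d.get("start", ""),
            "end": d.get("end", ""),
            "traits": d.get("traits", ""),
            "node_class": d.get("node_class", ""),
            "min_p": d.get("min_p", ""),
        })
    cols = ["id", "kind", "chrom", "start", "end", "traits", "node_class", "min_p"]
    return pd.DataFrame(rows, columns=cols).sort_values("id").reset_index(drop=True)


def edge_table(net: nx.Graph) -> pd.DataFrame:
    rows = [
        {"source": u, "target": v, "kind": d.get("kind", ""), "weight": d.get("weight", 1.0)}
        for u, v, d in net.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "kind", "weight"]).sort_values(
        ["source", "target"]).reset_index(drop=True)


def export_network(net: nx.Graph, outdir) -> dict[str, str]:
    """Write node/edge TSVs plus Cytoscape-loadable GraphML and SIF files."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": outdir / "network_nodes.tsv",
        "edges": outdir / "network_edges.tsv",
        "graphml": outdir / "network.graphml",
        "sif": outdir / "network.sif",
    }
    try:
        node_table(net).to_csv(paths["nodes"], sep="\t", index=False)
        edge_table(net).to_csv(paths["edges"], sep="\t", index=False)
        nx.write_graphml(net, paths["graphml"])
        with open(paths["sif"], "w") as fh:
            for u, v, d in net.edges(data=True):
                fh.write(f"{u}\t{d.get('kind', 'edge')}\t{v}\n")
    except OSError as exc:
        raise OSError(f"network export failed at {exc.filename}: {exc}") from exc
    return {k: str(v) for k, v in paths.items()}


def read_network_tables(nodes_path, edges_path) -> nx.Graph:
    """Rebuild a network from the exported node/edge TSVs (round trip)."""
    g = nx.Graph()
    nodes = pd.read_csv(nodes_path, sep="\t", keep_default_na=False)
    edges = pd.read_csv(edges_path, sep="\t", keep_default_na=False)
    for _, r in nodes.iterrows():
        attrs = {"kind": r["kind"]}
        if r["kind"] == "qtl":
            attrs.update(
                chrom=str(r["chrom"]), start=int(r["start"]), end=int(r["end"]),
                traits=str(r["traits"]), node_class=str(r["node_class"]),
                min_p=float(r["min_p"]),
            )
        g.add_node(r["id"], **attrs)
    for _, r in edges.iterrows():
        g.add_edge(r["source"], r["target"], kind=r["kind"], weight=float(r["weight"]))
    return g


__all__ = [
    "NODE_CLASSES",
    "QTLNode",
    "inter_ld",
    "merge_overlapping_qtls",
    "build_network",
    "classify_counts",
    "node_table",
    "edge_table",
    "export_network",
    "read_network_tables",
]
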