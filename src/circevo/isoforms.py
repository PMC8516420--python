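"""Splicing-graph reconstruction of circRNA internal exon structure.

RNase R enrichment is measured per splice junction as the log2 change of
size-factor-normalized coverage (treated over untreated).  Junctions
outside the backsplice span of a gene form an empirical background
distribution; inside junctions whose change falls outside the central 90%
interval of that background are assigned to the circRNA.  Assigned
junctions become edges of a directed acyclic splicing graph whose nodes
are the annotated exons inside the circle span (in genomic order — the
score of a path is orientation-invariant); all source-to-sink paths are
enumerated breadth-first and the path with the highest mean edge weight is
the reconstructed (strongest) isoform.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np

from circevo.formats import GeneModel, GenomicInterval


@dataclass(frozen=True)
class JunctionChange:
    junction: tuple[str, int]  # (gene_id, junction index)
    location: str  # inside_bsj | outside_bsj
    log2_change: float


def background_interval(
    outside_changes, coverage: float = 0.90
) -> tuple[float, float]:
    """Empirical central interval of the background log2 changes.

    With the default coverage this is the (5th, 95th) percentile pair,
    computed with linear interpolation on the order statistics.
    """
    vals = np.asarray([v for v in outside_changes if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("empty background distribution")
    tail = 100.0 * (1.0 - coverage) / 2.0
    lo, hi = np.percentile(vals, [tail, 100.0 - tail])
    return float(lo), float(hi)


def assign_circ_junctions(
    inside: list[JunctionChange], interval: tuple[float, float]
) -> list[JunctionChange]:
    """Inside-backsplice junctions falling strictly outside the background
    interval are assigned to the circRNA; -inf (treated count 0) never is."""
    lo, hi = interval
    return [
        jc
        for jc in inside
        if np.isfinite(jc.log2_change) and (jc.log2_change < lo or jc.log2_change > hi)
    ]


def strongest_isoform(graph: nx.DiGraph, source, sink) -> tuple[list, float]:
    """Best source-to-sink path by mean edge weight.

    All paths are enumerated by breadth-first traversal (the graphs are
    small DAGs).  Ties are broken toward more exons, then lexicographically
    smaller node sequences.  With no path the backsplice boundary exons
    alone are returned with zero coverage (a single exon when they
    coincide).
    """
    if source == sink:
        return [source], 0.0
    best: tuple | None = None
    best_path: list | None = None
    queue = deque([(source, (source,), 0.0, 0)])
    while queue:
        node, path, wsum, nedges = queue.popleft()
        if node == sink:
            mean = wsum / nedges
            key = (-mean, -len(path), path)
            if best is None or key < best:
                best, best_path = key, list(path)
            continue
        for nxt in graph.successors(node):
            if nxt in path:
                continue  # guard against accidental cycles
            w = graph.edges[node, nxt].get("weight", 0.0)
            queue.append((nxt, path + (nxt,), wsum + w, nedges + 1))
    if best_path is None:
        return [source, sink], 0.0
    return best_path, -best[0]


@dataclass
class IsoformResult:
    circ_id: str
    gene_id: str
    exons: list[GenomicInterval]
    mean_coverage: float
    n_assigned_junctions: int


def junction_changes(
    junction_norm_means: dict[tuple[str, int], tuple[float, float]],
    gene_spans: dict[tuple[str, int], tuple[int, int]],
    circ: GenomicInterval,
    gene_id: str,
) -> tuple[list[JunctionChange], list[JunctionChange]]:
    """Split a gene's junction changes into inside/outside the backsplice.

    ``junction_norm_means`` maps (gene, junction index) to normalized
    (untreated_mean, treated_mean); ``gene_spans`` gives each junction's
    genomic (donor_end, acceptor_start) span.  Junctions with no coverage
    in either condition are skipped.
    """
    inside, outside = [], []
    for key, (u, t) in junction_norm_means.items():
        if key[0] != gene_id:
            continue
        if u == 0 and t == 0:
            continue
        if u == 0:
            continue  # no untreated baseline: uninformative
        change = np.log2(t / u) if t > 0 else -np.inf
        lo, hi = gene_spans[key]
        loc = (
            "inside_bsj"
            if circ.start <= lo and hi <= circ.end
            else "outside_bsj"
        )
        jc = JunctionChange(key, loc, float(change))
        (inside if loc == "inside_bsj" else outside).append(jc)
    return inside, outside


def build_splice_graph(
    exons: list[GenomicInterval],
    assigned: list[JunctionChange],
    junction_exons: dict[tuple[str, int], tuple[int, int]],
    treated_cov: dict[tuple[str, int], float],
) -> nx.DiGraph:
    """Nodes are circle-span exons; edges are assigned circRNA junctions
    weighted by treated-condition normalized coverage."""
    g = nx.DiGraph()
    for e in exons:
        g.add_node((e.start, e.end))
    index_of = {i: (e.start, e.end) for i, e in enumerate(exons)}
    for jc in assigned:
        a, b = junction_exons[jc.junction]
        if a in index_of and b in index_of:
            g.add_edge(index_of[a], index_of[b],
                       weight=treated_cov.get(jc.junction, 0.0))
    return g


def reconstruct_circ_isoform(
    circ: GenomicInterval,
    circ_id: str,
    gene: GeneModel,
    junction_norm_means: dict[tuple[str, int], tuple[float, float]],
    background: list[JunctionChange],
    coverage: float = 0.90,
    min_background: int = 20,
    global_background: list[JunctionChange] | None = None,
) -> IsoformResult:
    """Reconstruct one circRNA's strongest isoform.

    Background is pooled per gene when at least ``min_background`` outside
    junctions exist, otherwise the supplied global background is used.
    """
    exons_all = gene.collapsed_exons()
    span_exons = [e for e in exons_all if e.start >= circ.start and e.end <= circ.end]
    if not span_exons:
        span_exons = [e for e in exons_all if e.overlap(circ) > 0]
    junction_spans = {}
    junction_exons = {}
    for i in range(len(exons_all) - 1):
        key = (gene.gene_id, i)
        junction_spans[key] = (exons_all[i].end, exons_all[i + 1].start)
        junction_exons[key] = (
            exons_all.index(exons_all[i]),
            exons_all.index(exons_all[i + 1]),
        )
    inside, outside = junction_changes(
        junction_norm_means, junction_spans, circ, gene.gene_id
    )
    bg = [jc.log2_change for jc in background + outside]
    if len(bg) < min_background and global_background is not None:
        bg = [jc.log2_change for jc in global_background]
    interval = background_interval(bg, coverage)
    assigned = assign_circ_junctions(inside, interval)
    treated_cov = {
        key: t for key, (_, t) in junction_norm_means.items()
    }
    # re-index span exons relative to the full exon list
    span_idx = [exons_all.index(e) for e in span_exons]
    g = nx.DiGraph()
    for e in span_exons:
        g.add_node((e.start, e.end))
    for jc in assigned:
        a, b = junction_exons[jc.junction]
        if a in span_idx and b in span_idx:
            ea, eb = exons_all[a], exons_all[b]
            g.add_edge((ea.start, ea.end), (eb.start, eb.end),
                       weight=treated_cov.get(jc.junction, 0.0))
    source = (span_exons[0].start, span_exons[0].end)
    sink = (span_exons[-1].start, span_exons[-1].end)
    path, mean_cov = strongest_isoform(g, source, sink)
    exon_ivs = [GenomicInterval(gene.chrom, s, e, gene.strand) for s, e in path]
    return IsoformResult(
        circ_id=circ_id,
        gene_id=gene.gene_id,
        exons=exon_ivs,
        mean_coverage=mean_cov,
        n_assigned_junctions=len(assigned),
    )
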