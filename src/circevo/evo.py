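"""Cross-species circRNA locus sharing, clade grouping and hotspots.

CircRNAs are collapsed per gene into loci (exon unions); loci are lifted
between species through chain maps (an exon lifts when at least half of
its bases fall into aligned blocks) and connected at three increasingly
strict levels: (1) 1:1 orthologous parental genes, (2) additionally at
least one shared exon after lifting, independent of exon length, (3)
additionally shared start and stop exons of a circRNA in both species.
Sharing graphs are partitioned with the Markov Cluster algorithm
(inflation 2.0, unit edge weights) and each cluster receives a clade label
from its species composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from circevo.formats import ChainMap, GenomicInterval, merge_intervals

CLADE_LABELS = ("species-specific", "rodent", "primate", "eutherian", "therian")


@dataclass
class CircAnnotation:
    """A circRNA with its reconstructed exon chain and per-tissue CPM."""

    circ_id: str
    species: str
    gene_id: str
    exons: list[GenomicInterval]
    cpm: dict[str, float] = field(default_factory=dict)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.exons[0].chrom,
            self.exons[0].start,
            self.exons[-1].end,
            self.exons[0].strand,
        )


@dataclass
class CircLocus:
    """Per-gene union of circRNA exons plus the member circRNAs."""

    gene_id: str
    species: str
    exons: list[GenomicInterval]
    members: list[CircAnnotation]

    @property
    def key(self) -> tuple[str, str]:
        return (self.species, self.gene_id)


def collapse_loci(circs: list[CircAnnotation]) -> list[CircLocus]:
    """Collapse each gene's circRNA exons into a single merged locus."""
    by_gene: dict[tuple[str, str], list[CircAnnotation]] = {}
    for c in circs:
        by_gene.setdefault((c.species, c.gene_id), []).append(c)
    loci = []
    for (species, gene_id), members in sorted(by_gene.items()):
        exons = merge_intervals(e for c in members for e in c.exons)
        loci.append(CircLocus(gene_id, species, exons, members))
    return loci


def lift_locus(
    locus: CircLocus, chain: ChainMap, min_match: float = 0.5
) -> dict[GenomicInterval, GenomicInterval | None]:
    """Lift each exon of a locus; failed exons map to None."""
    return {e: chain.lift(e, min_match) for e in locus.exons}


def _lift_overlaps(
    exon: GenomicInterval,
    chain: ChainMap,
    targets: list[GenomicInterval],
    min_match: float,
) -> bool:
    lifted = chain.lift(exon, min_match)
    if lifted is None:
        return False
    return any(lifted.overlap(t) > 0 for t in targets)


def shared_level(
    loci: list[CircLocus],
    level: int,
    ortho_family: dict[tuple[str, str], str],
    chains: dict[tuple[str, str], ChainMap],
    min_match: float = 0.5,
) -> nx.Graph:
    """Pairwise shared/not-shared graph between loci at a given level.

    Levels nest: a level-3 edge implies level-2 implies level-1 for the
    same pair.  Level 1 requires 1:1 orthologous parental genes; level 2
    additionally one shared exon after lifting (any overlap, independent of
    exon length, with reciprocal lift success); level 3 additionally that
    the lifted start and stop exons are start/stop exons of a circRNA in
    the partner species.
    """
    if level not in (1, 2, 3):
        raise ValueError("level must be 1, 2 or 3")
    g = nx.Graph()
    for locus in loci:
        g.add_node(locus.key, locus=locus)
    by_key = {locus.key: locus for locus in loci}
    keys = sorted(by_key)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            a, b = by_key[ka], by_key[kb]
            if a.species == b.species:
                continue
            fam_a = ortho_family.get(ka)
            fam_b = ortho_family.get(kb)
            if fam_a is None or fam_a != fam_b:
                continue
            if level == 1:
                g.add_edge(ka, kb)
                continue
            ab = chains.get((a.species, b.species))
            ba = chains.get((b.species, a.species))
            if ab is None or ba is None:
                continue
            shared_exon = any(
                _lift_overlaps(e, ab, b.exons, min_match) for e in a.exons
            ) and any(_lift_overlaps(e, ba, a.exons, min_match) for e in b.exons)
            if not shared_exon:
                continue
            if level == 2:
                g.add_edge(ka, kb)
                continue
            # level 3: start/stop exons of some circRNA pair must correspond
            ok = False
            for ca in a.members:
                start_a, stop_a = ca.exons[0], ca.exons[-1]
                for cb in b.members:
                    starts_b = [cb.exons[0]]
                    stops_b = [cb.exons[-1]]
                    if _lift_overlaps(start_a, ab, starts_b, min_match) and _lift_overlaps(
                        stop_a, ab, stops_b, min_match
                    ):
                        ok = True
                        break
                if ok:
                    break
            if ok:
                g.add_edge(ka, kb)
    return g


def write_abc(graph: nx.Graph, path, weight: float = 1.0) -> None:
    """Write a sharing graph in abc format (node, node, connection strength)
    for interoperability with external clustering tools."""
    with open(path, "w") as fh:
        for a, b in sorted(graph.edges()):
            fh.write(f"{_node_label(a)}\t{_node_label(b)}\t{weight:g}\n")


def _node_label(node) -> str:
    if isinstance(node, tuple):
        return ":".join(map(str, node))
    return str(node)


# ---------------------------------------------------------------------------
# Markov clustering


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[list[set], bool]:
    """Markov Cluster algorithm on a unit-weight graph.

    Self-loops are added, columns normalized, and expansion (matrix square)
    alternates with inflation (elementwise power, renormalize) until the
    matrix is stable.  Clusters are built from attractors (nodes with
    positive diagonal mass): the nodes reached by each attractor row are
    one cluster, and clusters sharing any node are merged so the output is
    a partition of all nodes.  Returns (partition, converged).
    """
    nodes = sorted(graph.nodes())
    n = len(nodes)
    if n == 0:
        return [], True
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.eye(n)
    for a, b in graph.edges():
        if a == b:
            continue
        m[idx[a], idx[b]] = 1.0
        m[idx[b], idx[a]] = 1.0
    m /= m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded**inflation
        inflated /= inflated.sum(axis=0, keepdims=True)
        if np.abs(inflated - m).max() < tol:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        warnings.warn("MCL did not converge; returning current state")
    # attractor-based cluster extraction
    thresh = 1e-6
    attractors = [i for i in range(n) if m[i, i] > thresh]
    clusters: list[set[int]] = []
    for a in attractors:
        reached = {j for j in range(n) if m[a, j] > thresh} | {a}
        merged = False
        for cl in clusters:
            if cl & reached:
                cl |= reached
                merged = True
                break
        if merged:
            # merging may chain further
            changed = True
            while changed:
                changed = False
                for i in range(len(clusters)):
                    for j in range(i + 1, len(clusters)):
                        if clusters[i] & clusters[j]:
                            clusters[i] |= clusters[j]
                            del clusters[j]
                            changed = True
                            break
                    if changed:
                        break
        else:
            clusters.append(set(reached))
    assigned = set().union(*clusters) if clusters else set()
    for i in range(n):
        if i not in assigned:
            clusters.append({i})
    out = [{nodes[i] for i in cl} for cl in clusters]
    # partition guarantee
    flat = [v for cl in out for v in cl]
    assert len(flat) == n and len(set(flat)) == n
    return out, converged


def clade_assign(cluster_species: set[str], clade_of: dict[str, str]) -> str:
    """Clade label from the species composition of a cluster.

    Therian: the marsupial plus at least three of the four non-marsupial
    species; eutherian: at least three of the four non-marsupials (with or
    without full membership); rodent/primate: both species of the lineage;
    otherwise species-specific.
    """
    marsupials = {s for s in cluster_species if clade_of.get(s) == "marsupial"}
    rodents = {s for s in cluster_species if clade_of.get(s) == "rodent"}
    primates = {s for s in cluster_species if clade_of.get(s) == "primate"}
    n_eutherian = len(rodents) + len(primates)
    if marsupials and n_eutherian >= 3:
        return "therian"
    if n_eutherian >= 3:
        return "eutherian"
    all_rodents = {s for s, c in clade_of.items() if c == "rodent"}
    all_primates = {s for s, c in clade_of.items() if c == "primate"}
    if all_rodents and rodents == all_rodents:
        return "rodent"
    if all_primates and primates == all_primates:
        return "primate"
    return "species-specific"


@dataclass
class OrthologyGroup:
    member_loci: list[CircLocus]
    clade_label: str


def cluster_loci(
    loci: list[CircLocus],
    ortho_family: dict[tuple[str, str], str],
    chains: dict[tuple[str, str], ChainMap],
    clade_of: dict[str, str],
    level: int = 2,
    inflation: float = 2.0,
) -> list[OrthologyGroup]:
    """Shared-locus graph (level 2 by default) -> MCL -> clade labels."""
    graph = shared_level(loci, level, ortho_family, chains)
    partition, _ = mcl_cluster(graph, inflation)
    by_key = {locus.key: locus for locus in loci}
    groups = []
    for cluster in partition:
        members = [by_key[k] for k in sorted(cluster)]
        label = clade_assign({k[0] for k in cluster}, clade_of)
        groups.append(OrthologyGroup(members, label))
    return groups


# ---------------------------------------------------------------------------
# hotspots and expression classes


@dataclass
class Hotspot:
    gene_id: str
    species: str
    n_circ: int
    top_shares: dict[str, tuple[float, float]]  # tissue -> (top1, top2) share


def call_hotspots(
    circs: list[CircAnnotation],
    cpm_thresholds: tuple[float, ...] = (0.01, 0.05, 0.1),
) -> dict[float, dict]:
    """Hotspot tables at several CPM thresholds.

    A gene is a hotspot when it hosts at least two distinct, overlapping
    circRNAs passing the threshold in some tissue.  Each table reports the
    hotspot genes, the fraction of circRNA loci that are hotspots, the
    fraction of circRNAs originating from hotspots, the mean number of
    circRNAs per hotspot, and per-tissue top-1/top-2 expression shares.
    """
    out: dict[float, dict] = {}
    for thr in cpm_thresholds:
        passing = [
            c for c in circs if any(v >= thr for v in c.cpm.values())
        ]
        by_gene: dict[tuple[str, str], list[CircAnnotation]] = {}
        for c in passing:
            by_gene.setdefault((c.species, c.gene_id), []).append(c)
        hotspots: list[Hotspot] = []
        n_circ_from_hotspots = 0
        for (species, gene_id), members in sorted(by_gene.items()):
            distinct = {tuple((e.start, e.end) for e in c.exons) for c in members}
            overlapping = len(members) >= 2 and any(
                a.span.overlap(b.span) > 0
                for i, a in enumerate(members)
                for b in members[i + 1 :]
            )
            if len(distinct) >= 2 and overlapping:
                tissues = {t for c in members for t in c.cpm}
                shares = {}
                for t in tissues:
                    vals = sorted(
                        (c.cpm.get(t, 0.0) for c in members), reverse=True
                    )
                    total = sum(vals)
                    if total > 0:
                        top1 = vals[0] / total
                        top2 = (vals[0] + vals[1]) / total if len(vals) > 1 else top1
                        shares[t] = (top1, top2)
                hotspots.append(Hotspot(gene_id, species, len(members), shares))
                n_circ_from_hotspots += len(members)
        n_loci = len(by_gene)
        out[thr] = {
            "hotspots": hotspots,
            "pct_loci_hotspot": 100.0 * len(hotspots) / n_loci if n_loci else 0.0,
            "pct_circ_from_hotspots": (
                100.0 * n_circ_from_hotspots / len(passing) if passing else 0.0
            ),
            "mean_circ_per_hotspot": (
                float(np.mean([h.n_circ for h in hotspots])) if hotspots else 0.0
            ),
        }
    return out


def high_expression_split(
    circs: list[CircAnnotation], quantile: float = 0.90
) -> dict[str, str]:
    """Label circRNAs 'high' when above the per-tissue CPM quantile in any
    tissue (union across tissues), else 'low'."""
    high: set[str] = set()
    tissues = sorted({t for c in circs for t in c.cpm})
    for t in tissues:
        expressed = [(c.circ_id, c.cpm[t]) for c in circs if c.cpm.get(t, 0.0) > 0]
        if len(expressed) < 10:
            continue
        cut = np.percentile([v for _, v in expressed], 100.0 * quantile)
        high |= {cid for cid, v in expressed if v > cut}
    return {c.circ_id: ("high" if c.circ_id in high else "low") for c in circs}
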