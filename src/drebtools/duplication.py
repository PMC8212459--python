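"""Tandem-duplication detection by chromosomal windowing.

A tandem duplication event is a chromosomal region within a fixed window
(default 200 kb) containing two or more homologous family members. Clusters
are the connected components of the graph joining same-chromosome gene
pairs that are homologous and within the window of each other; family
members with only inter-chromosomal or beyond-window homology are labelled
segmental/WGD candidates (full collinearity inference is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import protein_identity
from .records import GeneModel, SequenceRecord

DEFAULT_WINDOW = 200_000
DEFAULT_MIN_IDENTITY = 0.4


@dataclass(frozen=True)
class HomologyEdge:
    gene_a: str
    gene_b: str
    identity: float
    source: str = "provided"  # provided | computed

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be within [0, 1]")


@dataclass(frozen=True)
class TandemCluster:
    cluster_id: int
    chromosome: str
    members: tuple[str, ...]  # gene ids ordered by start
    spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a tandem cluster needs >= 2 members")


def compute_edges(
    genes: list[GeneModel], proteins: dict[str, SequenceRecord]
) -> list[HomologyEdge]:
    """All-vs-all global-identity homology edges (identity > 0 recorded)."""
    edges = []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            ident = protein_identity(proteins[a.protein_id], proteins[b.protein_id])
            edges.append(HomologyEdge(a.gene_id, b.gene_id, ident, "computed"))
    return edges


def _gap(a: GeneModel, b: GeneModel) -> int:
    """End-of-upstream to start-of-downstream separation (bp); <= 0 when
    the genes touch or overlap."""
    first, second = (a, b) if a.start <= b.start else (b, a)
    return second.start - first.end


def tandem_clusters(
    genes: list[GeneModel],
    edges: list[HomologyEdge] | None = None,
    window: int = DEFAULT_WINDOW,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[TandemCluster]:
    """Find tandem clusters among one family's genes.

    With ``edges=None`` every same-chromosome pair is treated as homologous
    (pure-distance mode); otherwise pairs must carry an edge with identity
    >= ``min_identity``. Cluster ids are assigned in (chromosome, start)
    order; singletons are dropped. Deterministic and independent of input
    order.
    """
    for g in genes:
        if not g.chromosome or g.chromosome.lower() in ("unknown", "na", "."):
            raise ValueError(f"gene {g.gene_id!r} has unknown chromosome")

    genes = sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id))
    homolog: set[frozenset[str]] | None = None
    if edges is not None:
        homolog = {
            frozenset((e.gene_a, e.gene_b))
            for e in edges
            if e.identity >= min_identity
        }

    parent = {g.gene_id: g.gene_id for g in genes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if a.chromosome != b.chromosome:
                continue
            if _gap(a, b) > window:
                continue
            if homolog is not None and frozenset((a.gene_id, b.gene_id)) not in homolog:
                continue
            parent[find(a.gene_id)] = find(b.gene_id)

    components: dict[str, list[GeneModel]] = {}
    for g in genes:
        components.setdefault(find(g.gene_id), []).append(g)

    clusters = []
    ordered = sorted(
        (sorted(v, key=lambda g: g.start) for v in components.values() if len(v) >= 2),
        key=lambda ms: (ms[0].chromosome, ms[0].start),
    )
    for cid, members in enumerate(ordered, start=1):
        clusters.append(
            TandemCluster(
                cluster_id=cid,
                chromosome=members[0].chromosome,
                members=tuple(g.gene_id for g in members),
                spans=tuple((g.start, g.end) for g in members),
            )
        )
    return clusters


def classify_duplication(
    genes: list[GeneModel],
    clusters: list[TandemCluster],
    edges: list[HomologyEdge] | None,
    window: int = DEFAULT_WINDOW,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> dict[str, str]:
    """Label every gene tandem, segmental/WGD-candidate, or none.

    Tandem-cluster members are tandem; genes with at least one
    inter-chromosomal or beyond-window homology edge are segmental/WGD
    candidates; the rest are none.
    """
    tandem = {gid for c in clusters for gid in c.members}
    by_id = {g.gene_id: g for g in genes}
    labels = {g.gene_id: "none" for g in genes}
    for gid in tandem:
        labels[gid] = "tandem"

    if edges is None:
        edges = [
            HomologyEdge(a.gene_id, b.gene_id, 1.0, "provided")
            for i, a in enumerate(genes)
            for b in genes[i + 1 :]
        ]
    for e in edges:
        if e.identity < min_identity:
            continue
        if e.gene_a not in by_id or e.gene_b not in by_id:
            continue
        a, b = by_id[e.gene_a], by_id[e.gene_b]
        distal = a.chromosome != b.chromosome or _gap(a, b) > window
        if distal:
            for gid in (e.gene_a, e.gene_b):
                if labels[gid] != "tandem":
                    labels[gid] = "segmental/WGD-candidate"
    return labels


def chromosome_summary(genes: list[GeneModel]) -> pd.DataFrame:
    """Per-chromosome gene counts plus haplotype-collapsed counts.

    ``Chr2A``/``Chr2B``... collapse to ``Chr2`` in the ``collapsed`` column.
    """
    from .classify import _chrom_parts

    if not genes:
        return pd.DataFrame(columns=["chromosome", "count", "collapsed", "collapsed_count"])
    per = pd.Series([g.chromosome for g in genes]).value_counts().sort_index()
    collapsed_name = {
        chrom: f"Chr{_chrom_parts(chrom)[0]}" if _chrom_parts(chrom)[1] else chrom
        for chrom in per.index
    }
    collapsed = (
        pd.Series([collapsed_name[g.chromosome] for g in genes])
        .value_counts()
        .sort_index()
    )
    return pd.DataFrame(
        {
            "chromosome": per.index,
            "count": per.values,
            "collapsed": [collapsed_name[c] for c in per.index],
            "collapsed_count": [collapsed[collapsed_name[c]] for c in per.index],
        }
    )
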