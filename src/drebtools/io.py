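"""Readers/writers for every external format the pipeline touches.

All readers validate strictly and reject malformed input with an error that
carries the file position; nothing is silently repaired. Coordinates are
kept 1-based inclusive exactly as in the file.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import dendropy
from Bio import SeqIO

from .records import DomainHit, GeneModel, PhyloNode, SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_domtblout",
    "write_newick",
    "read_newick",
    "write_report",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path, alphabet: str = "protein", aligned: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Sequences are uppercased; order is preserved. Gap characters are only
    accepted when ``aligned=True``. Duplicate ids and illegal residues are
    errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(rec.id, str(rec.seq).upper(), alphabet, aligned=aligned)
        )
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------- GFF3

_ATTR_ID = re.compile(r"(?:^|;)ID=([^;]+)")


def read_gff3(path) -> list[GeneModel]:
    """Read gene features from a canonical GFF3 file.

    One :class:`GeneModel` per ``gene`` feature; the linked protein/CDS ids
    default to ``<ID>.p`` / ``<ID>.c`` unless ``protein_id=`` / ``cds_id=``
    attributes are present.
    """
    genes: list[GeneModel] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start > end:
                raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
            m = _ATTR_ID.search(attrs)
            if not m:
                raise ValueError(f"{path}:{lineno}: gene feature lacks ID attribute")
            gene_id = m.group(1)
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chromosome=seqid,
                    start=start,
                    end=end,
                    strand=strand if strand in ("+", "-") else "unknown",
                    protein_id=attr_map.get("protein_id", gene_id + ".p"),
                    cds_id=attr_map.get("cds_id", gene_id + ".c"),
                )
            )
    return genes


def write_gff3(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            strand = g.strand if g.strand in ("+", "-") else "."
            attrs = f"ID={g.gene_id};protein_id={g.protein_id};cds_id={g.cds_id}"
            fh.write(
                f"{g.chromosome}\tdrebtools\tgene\t{g.start}\t{g.end}\t.\t"
                f"{strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------- domtblout

_AP2_NAMES = {"PF00847", "AP2", "AP2/ERF"}
_B3_NAMES = {"PF02362", "B3"}


def _domain_kind(query_name: str, query_acc: str) -> str:
    acc = query_acc.split(".")[0]
    if query_name in _AP2_NAMES or acc in _AP2_NAMES:
        return "AP2"
    if query_name in _B3_NAMES or acc in _B3_NAMES:
        return "B3"
    return "other"


def read_domtblout(path) -> list[DomainHit]:
    """Parse an HMMER ``--domtblout`` table into :class:`DomainHit` rows.

    Envelope coordinates (columns 20/21) are used as the domain extent.
    The query name/accession is mapped to AP2 (PF00847), B3 (PF02362) or
    ``other``.
    """
    hits: list[DomainHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise ValueError(
                    f"{path}:{lineno}: malformed domtblout row "
                    f"({len(fields)} columns, need >= 22)"
                )
            try:
                env_from, env_to = int(fields[19]), int(fields[20])
                score = float(fields[13])
                evalue = float(fields[12])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed numeric field"
                ) from None
            hits.append(
                DomainHit(
                    protein_id=fields[0],
                    domain_name=_domain_kind(fields[3], fields[4]),
                    start=env_from,
                    end=env_to,
                    score=score,
                    evalue=evalue,
                )
            )
    return hits


def write_domtblout(hits, path) -> None:
    """Write hits in a minimal domtblout-compatible layout (22 columns)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# target name " + "-" * 40 + "\n")
        acc = {"AP2": "PF00847.21", "B3": "PF02362.1"}
        for h in hits:
            ev = h.evalue if h.evalue is not None else 1e-30
            sc = h.score if h.score is not None else 100.0
            cols = [
                h.protein_id, "-", "0", h.domain_name,
                acc.get(h.domain_name, "-"), "0", str(ev), str(sc), "0.0",
                "1", "1", str(ev), str(ev), str(sc), "0.0",
                "1", str(h.length), str(h.start), str(h.end),
                str(h.start), str(h.end), "0.99",
            ]
            fh.write(" ".join(cols) + "\n")


# ---------------------------------------------------------------- newick

def _newick_node(node: PhyloNode) -> str:
    if node.is_leaf:
        if not node.name:
            raise ValueError("newick export: unlabeled leaf")
        label = node.name
    else:
        inner = ",".join(_newick_node(c) for c in node.children)
        support = "" if node.support is None else format(node.support, ".10g")
        label = f"({inner}){support}"
    if node.length is not None:
        label += f":{node.length:.10g}"
    return label


def write_newick(tree: PhyloNode) -> str:
    """Serialise a tree to a newick string with branch lengths and optional
    internal-node support values."""
    names = tree.leaf_names()
    if len(names) != len(set(names)):
        raise ValueError("newick export: leaf labels must be unique")
    return _newick_node(tree) + ";"


def read_newick(text: str) -> PhyloNode:
    """Parse a newick string (via dendropy) into a :class:`PhyloNode` tree."""
    dtree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )

    def convert(dnode) -> PhyloNode:
        name = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
        support = None
        if dnode.label and not dnode.is_leaf():
            try:
                support = float(dnode.label)
            except ValueError:
                support = None
        node = PhyloNode(
            name=name if dnode.is_leaf() else "",
            length=dnode.edge.length,
            support=support,
        )
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return convert(dtree.seed_node)


# ---------------------------------------------------------------- reports

def write_report(results: dict, path) -> None:
    """Write an analysis report as stable, sorted-key JSON (UTF-8)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")
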