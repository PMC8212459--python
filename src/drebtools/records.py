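"""Internal record model shared by every pipeline stage.

Coordinates are 1-based inclusive throughout (GFF3 convention); strand is
carried but never used to flip coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")
GAP = "-"


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein or DNA sequence.

    ``alphabet`` is ``"protein"`` or ``"dna"``; ``X`` (protein) and ``N``
    (DNA) mark unknown residues and are excluded from pairwise computations
    downstream. Gap characters are only legal when ``aligned=True``.
    """

    id: str
    sequence: str
    alphabet: str = "protein"
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if self.alphabet not in ("protein", "dna"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        if self.aligned:
            allowed = allowed | {GAP}
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"illegal {self.alphabet} residue {ch!r} at position {pos} "
                    f"in record {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def ungapped(self) -> str:
        return self.sequence.replace(GAP, "")


@dataclass(frozen=True)
class GeneModel:
    """A gene/allele with chromosomal coordinates and linked sequence ids."""

    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive bp
    end: int  # 1-based inclusive bp
    strand: str = "+"
    protein_id: str = ""
    cds_id: str = ""

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError(f"gene {self.gene_id!r}: chromosome must be non-empty")
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainHit:
    """A protein-domain hit (HMMER-style envelope coordinates, 1-based)."""

    protein_id: str
    domain_name: str  # "AP2", "B3" or "other"
    start: int
    end: int
    score: float | None = None
    evalue: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"domain hit on {self.protein_id!r}: bad span "
                f"{self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PhyloNode:
    """Node of an (in general unrooted, stored rooted-at-trifurcation) tree."""

    name: str = ""
    length: float | None = None
    support: float | None = None
    children: list["PhyloNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["PhyloNode"]:
        if self.is_leaf:
            return [self]
        out: list[PhyloNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalised to the side NOT containing
        the lexicographically first leaf label."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self.preorder():
            if node is self or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            if anchor in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(side)
        return splits
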