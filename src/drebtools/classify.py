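"""AP2/ERF superfamily decision tree and DREB subgroup diagnostics.

The decision tree mirrors the standard Arabidopsis-derived scheme:

* >= 2 AP2 domains                      -> AP2 subfamily
* an AP2 domain plus a B3 domain        -> RAV subfamily
* one AP2 domain without the WLG motif  -> atypical (excluded from DREB/ERF)
* one AP2 domain with WLG               -> DREB candidate (Group A) when the
  domain's 14th residue is valine, ERF (Group B) when it is alanine, with a
  consensus-similarity fallback otherwise.

DREB candidates are then split into the canonical A-1 (DREB1) and A-2
(DREB2) subgroups by the motif context of the domain: a DREB1-type NLS
immediately upstream for A-1, the CMIV-1 core upstream for A-2.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

from Bio.Align import PairwiseAligner

from .motifs import (
    CMIV1,
    DREB1_NLS,
    DREB2_NLS,
    DSAW,
    ERF_DOMAIN_CONSENSUS,
    DREB_DOMAIN_CONSENSUS,
    LWSY,
    WLG,
    scan_motif,
)
from .records import DomainHit, GeneModel, SequenceRecord

__all__ = [
    "ClassifiedGene",
    "classify_superfamily",
    "subgroup_dreb",
    "check_v14_e19",
    "group_alleles",
    "assign_names",
    "physchem_profile_row",
]


@dataclass
class ClassifiedGene:
    protein_id: str
    superfamily: str  # AP2 | RAV | DREB-candidate | ERF | atypical
    subgroup: str = "unassigned"  # A-1 | A-2 | other-A | unassigned
    n_ap2_domains: int = 0
    has_b3: bool = False
    flags: dict = field(default_factory=dict)
    domain: DomainHit | None = None

    def __post_init__(self) -> None:
        if self.superfamily == "AP2" and self.n_ap2_domains < 2:
            raise ValueError("AP2 subfamily requires >= 2 AP2 domains")
        if self.superfamily == "RAV" and not self.has_b3:
            raise ValueError("RAV subfamily requires a B3 domain")
        if self.subgroup != "unassigned" and self.superfamily != "DREB-candidate":
            raise ValueError("subgroups apply only to DREB candidates")


def check_v14_e19(protein: SequenceRecord, hit: DomainHit) -> tuple[str, str]:
    """Residues at domain-relative positions 14 and 19 (first residue of the
    hit counts as position 1)."""
    if hit.length < 19:
        raise ValueError(
            f"domain on {protein.id!r} has length {hit.length} < 19"
        )
    seq = protein.sequence
    return seq[hit.start - 1 + 13], seq[hit.start - 1 + 18]


def _similarity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


def classify_superfamily(
    protein: SequenceRecord, hits: list[DomainHit]
) -> ClassifiedGene:
    """Apply the superfamily decision tree to one protein and its domain hits."""
    own = [h for h in hits if h.protein_id == protein.id]
    if len(own) != len(hits):
        raise ValueError(
            f"domain hits for {protein.id!r} include foreign protein ids"
        )
    ap2 = sorted((h for h in own if h.domain_name == "AP2"), key=lambda h: h.start)
    b3 = [h for h in own if h.domain_name == "B3"]
    if not ap2:
        raise ValueError(f"{protein.id!r} is not an AP2/ERF-superfamily protein")

    if len(ap2) >= 2:
        return ClassifiedGene(protein.id, "AP2", n_ap2_domains=len(ap2),
                              has_b3=bool(b3), domain=ap2[0])
    if b3:
        return ClassifiedGene(protein.id, "RAV", n_ap2_domains=1,
                              has_b3=True, domain=ap2[0])

    hit = ap2[0]
    domain_seq = protein.sequence[hit.start - 1 : hit.end]
    wlg = bool(scan_motif(domain_seq, WLG))
    flags = {"wlg": wlg}
    if not wlg:
        return ClassifiedGene(protein.id, "atypical", n_ap2_domains=1,
                              flags=flags, domain=hit)

    v14, e19 = check_v14_e19(protein, hit)
    flags.update(v14=v14, e19=e19)
    if v14 == "V":
        fam = "DREB-candidate"
    elif v14 == "A":
        fam = "ERF"
    else:
        dreb_sim = _similarity(domain_seq, DREB_DOMAIN_CONSENSUS)
        erf_sim = _similarity(domain_seq, ERF_DOMAIN_CONSENSUS)
        fam = "DREB-candidate" if dreb_sim >= erf_sim else "ERF"
    return ClassifiedGene(protein.id, fam, n_ap2_domains=1, flags=flags,
                          domain=hit)


def subgroup_dreb(
    classified: ClassifiedGene,
    protein: SequenceRecord,
    upstream_window: int = 30,
    downstream_window: int = 10,
    cterm_window: int = 15,
) -> ClassifiedGene:
    """Split a DREB candidate into subgroup A-1 (DREB1) or A-2 (DREB2).

    A-1: DREB1-type NLS ends within ``upstream_window`` residues of the
    domain start. A-2: CMIV-1 core likewise upstream. Both kinds of evidence
    at once is an ambiguity error. The DSAW (immediately downstream), LWSY
    (C-terminal window) and PKK-like-NLS flags are recorded regardless.
    """
    if classified.superfamily != "DREB-candidate":
        raise ValueError("subgroup_dreb applies to DREB candidates only")
    hit = classified.domain
    assert hit is not None
    seq = protein.sequence

    def upstream(matches: list[tuple[int, int]]) -> bool:
        lo = hit.start - 1 - upstream_window
        return any(lo <= end < hit.start for _s, end in matches)

    nls1 = upstream(scan_motif(protein, DREB1_NLS))
    cmiv1 = upstream(scan_motif(protein, CMIV1))
    nls2 = upstream(scan_motif(protein, DREB2_NLS))
    dsaw = any(
        hit.end < s <= hit.end + downstream_window
        for s, _e in scan_motif(protein, DSAW)
    )
    lwsy = any(s > len(seq) - cterm_window for s, _e in scan_motif(protein, LWSY))

    flags = dict(classified.flags)
    flags.update(dreb1_nls=nls1, dreb2_nls=nls2, cmiv1=cmiv1, dsaw=dsaw, lwsy=lwsy)

    if nls1 and cmiv1:
        raise ValueError(
            f"{protein.id!r}: ambiguous subgroup evidence "
            "(both DREB1-type NLS and CMIV-1 upstream of the domain)"
        )
    subgroup = "A-1" if nls1 else ("A-2" if cmiv1 else "unassigned")
    return replace(classified, subgroup=subgroup, flags=flags)


def physchem_profile_row(classified: ClassifiedGene, protein: SequenceRecord) -> dict:
    """Flat TSV-ready row: classification labels, motif flags and the
    physicochemical profile of one protein."""
    from .physchem import physchem

    row = dict(
        protein_id=classified.protein_id,
        superfamily=classified.superfamily,
        subgroup=classified.subgroup,
        n_ap2_domains=classified.n_ap2_domains,
        has_b3=classified.has_b3,
    )
    row.update({f"flag_{k}": v for k, v in classified.flags.items()})
    try:
        prof = physchem(protein)
        row.update(
            length_aa=prof.length_aa, mw=round(prof.mw, 2),
            pi=round(prof.pi, 2), gravy=round(prof.gravy, 3),
            aliphatic_index=round(prof.aliphatic_index, 2),
            instability_index=round(prof.instability_index, 2),
        )
    except ValueError:  # e.g. X residues: profile undefined
        row.update(length_aa=len(protein))
    return row


# ------------------------------------------------------------- alleles

_CHROM_RE = re.compile(r"^Chr(\d+)([A-Za-z]?)$", re.IGNORECASE)


def _chrom_parts(chromosome: str) -> tuple[str, str]:
    m = _CHROM_RE.match(chromosome)
    if m:
        return m.group(1), m.group(2).upper()
    return chromosome, ""


def protein_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Global pairwise identity: identities / aligned columns."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a.sequence, b.sequence)[0]
    counts = aln.counts()
    aligned = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / aligned if aligned else 0.0


def group_alleles(
    genes: list[GeneModel],
    proteins: dict[str, SequenceRecord],
    identity_threshold: float = 0.95,
) -> list[list[GeneModel]]:
    """Partition genes into loci: genes are co-allelic when they sit on
    homologous chromosomes (same chromosome number, different haplotype
    letter) and their proteins are globally >= ``identity_threshold``
    identical. The partition is the transitive closure; same-haplotype
    near-identical pairs are warned about and kept apart.
    """
    parent = {g.gene_id: g.gene_id for g in genes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            num_a, hap_a = _chrom_parts(a.chromosome)
            num_b, hap_b = _chrom_parts(b.chromosome)
            if num_a != num_b:
                continue
            ident = protein_identity(proteins[a.protein_id], proteins[b.protein_id])
            if ident < identity_threshold:
                continue
            if hap_a == hap_b:
                warnings.warn(
                    f"{a.gene_id} and {b.gene_id} are near-identical on the "
                    f"same haplotype {a.chromosome}; kept as separate loci"
                )
                continue
            parent[find(a.gene_id)] = find(b.gene_id)

    groups: dict[str, list[GeneModel]] = {}
    for g in genes:
        groups.setdefault(find(g.gene_id), []).append(g)
    loci = [sorted(v, key=lambda g: (g.chromosome, g.start)) for v in groups.values()]
    return sorted(loci, key=lambda locus: (locus[0].chromosome, locus[0].start))


def assign_names(
    loci: list[list[GeneModel]], prefix: str = "SsDREB1"
) -> dict[str, str]:
    """Letter loci A, B, C... in coordinate order of each locus's first
    allele; suffix alleles -1..-k within multi-allele loci."""
    ordered = sorted(loci, key=lambda locus: min((g.chromosome, g.start) for g in locus))
    if len(ordered) > 26:
        raise ValueError(f"{len(ordered)} loci exceed the single-letter range A-Z")
    names: dict[str, str] = {}
    for idx, locus in enumerate(ordered):
        letter = chr(ord("A") + idx)
        alleles = sorted(locus, key=lambda g: (g.chromosome, g.start))
        for k, gene in enumerate(alleles, start=1):
            suffix = f"-{k}" if len(alleles) > 1 else ""
            names[gene.gene_id] = f"{prefix}{letter}{suffix}"
    return names
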