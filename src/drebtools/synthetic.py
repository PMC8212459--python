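"""Synthetic fixtures with known ground truth for every pipeline stage.

Stands in for an external genome: proteins with planted domain
architectures and diagnostic motifs, a multi-chromosome gene map with
planted tandem clusters, codon pairs with controlled synonymous /
nonsynonymous divergence, and FPKM matrices with planted expression
patterns. Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .molevo import (
    CODON_TO_AA,
    NUCS,
    STOP_CODONS,
    syn_site_fraction,
    translate_codon,
)
from .motifs import CMIV1, DREB1_NLS, DREB2_NLS, B3_CORE, build_ap2_core
from .records import GeneModel, SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
SENSE_CODONS = sorted(set(CODON_TO_AA) - STOP_CODONS)

ARCHITECTURES = (
    "double-AP2",
    "AP2+B3",
    "single-AP2-with-WLG",
    "single-AP2-no-WLG",
)


# ------------------------------------------------------------ proteins

def _instantiate(pattern, rng, overrides: dict[int, str] | None = None) -> str:
    """Draw one concrete sequence from a degenerate pattern (seeded)."""
    overrides = overrides or {}
    out = []
    for k, pos_set in enumerate(pattern.positions, start=1):
        if k in overrides:
            out.append(overrides[k])
        elif len(pos_set) >= 20:  # wildcard
            out.append("A")
        else:
            out.append(rng.choice(sorted(pos_set)))
    return "".join(out)


def _bg(rng, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def build_protein_truth(
    architecture: str,
    motifs: set[str] | frozenset[str] = frozenset(),
    seed: int = 0,
    v14: str = "V",
    e19: str = "E",
    record_id: str = "synthetic",
) -> tuple[SequenceRecord, dict]:
    """Assemble a protein with the requested domain architecture and motifs,
    returning the record plus a truth dict of planted coordinates.

    The AP2 domain is realised as the 60-aa consensus core (so the
    consensus-scan fallback detector finds it); motifs are placed at
    non-overlapping positions in the windows where the classifier looks
    for them. Deterministic per seed.
    """
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    motifs = set(motifs)
    known = {"DREB1-NLS", "DREB2-NLS", "DSAW", "LWSY", "CMIV-1"}
    if motifs - known:
        raise ValueError(f"unknown motifs {sorted(motifs - known)}")
    if "DREB1-NLS" in motifs and motifs & {"CMIV-1", "DREB2-NLS"}:
        raise ValueError(
            "contradictory request: DREB1-type NLS together with DREB2 "
            "diagnostics would be ambiguous downstream"
        )
    if architecture == "single-AP2-no-WLG" and "DSAW" in motifs:
        raise ValueError(
            "contradictory request: DSAW adjacency implies a WLG-bearing domain"
        )

    rng = np.random.default_rng(seed)
    wlg = architecture != "single-AP2-no-WLG"
    flavor = "dreb" if v14 != "A" else "erf"
    core = build_ap2_core(v14=v14, e19=e19, wlg=wlg, flavor=flavor)

    truth: dict = {"architecture": architecture, "motifs": sorted(motifs)}
    parts: list[str] = [_bg(rng, 30, 60)]

    def cursor() -> int:
        return sum(len(p) for p in parts)

    # upstream motif block (NLS / CMIV-1), ending within 30 aa of the domain
    if "DREB1-NLS" in motifs:
        m = _instantiate(DREB1_NLS, rng)
        truth["DREB1-NLS"] = (cursor() + 1, cursor() + len(m))
        parts.append(m)
        parts.append(_bg(rng, 2, 8))
    elif "DREB2-NLS" in motifs:
        x14 = "K" if "CMIV-1" in motifs else "A"
        m = _instantiate(DREB2_NLS, rng, overrides={14: x14})
        truth["DREB2-NLS"] = (cursor() + 1, cursor() + len(m))
        if "CMIV-1" in motifs:
            truth["CMIV-1"] = (cursor() + 14, cursor() + 21)
        parts.append(m)
        parts.append(_bg(rng, 2, 6))
    elif "CMIV-1" in motifs:
        m = _instantiate(CMIV1, rng)
        truth["CMIV-1"] = (cursor() + 1, cursor() + len(m))
        parts.append(m)
        parts.append(_bg(rng, 2, 8))

    truth["domain"] = (cursor() + 1, cursor() + len(core))
    parts.append(core)

    if architecture == "double-AP2":
        parts.append(_bg(rng, 5, 15))
        second = build_ap2_core(v14=v14, e19=e19, wlg=True, flavor=flavor)
        truth["domain2"] = (cursor() + 1, cursor() + len(second))
        parts.append(second)
    elif architecture == "AP2+B3":
        parts.append(_bg(rng, 5, 15))
        truth["B3"] = (cursor() + 1, cursor() + len(B3_CORE))
        parts.append(B3_CORE)

    if "DSAW" in motifs:
        parts.append(_bg(rng, 2, 6))
        truth["DSAW"] = (cursor() + 1, cursor() + 4)
        parts.append("DSAW")

    parts.append(_bg(rng, 20, 40))

    if "LWSY" in motifs:
        truth["LWSY"] = (cursor() + 1, cursor() + 4)
        parts.append("LWSY")
        tail = int(rng.integers(0, 12))  # keep LWSY within the final 15 aa
        if tail:
            parts.append(_bg(rng, tail, tail))

    seq = "".join(parts)
    return SequenceRecord(record_id, seq, "protein"), truth


def make_protein(
    architecture: str,
    motifs: set[str] | frozenset[str] = frozenset(),
    seed: int = 0,
    **kwargs,
) -> SequenceRecord:
    return build_protein_truth(architecture, motifs, seed, **kwargs)[0]


def reverse_translate(protein: SequenceRecord, rng) -> SequenceRecord:
    """Pick a uniformly random synonymous codon per residue (seeded rng)."""
    by_aa: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        by_aa.setdefault(CODON_TO_AA[codon], []).append(codon)
    codons = [rng.choice(by_aa[aa]) for aa in protein.sequence]
    return SequenceRecord(protein.id + ".c", "".join(codons), "dna")


# ------------------------------------------------------------ genome fixture

@dataclass
class FixtureSpec:
    seed: int = 0
    n_chromosomes: int = 4
    genes_per_family: dict = field(
        default_factory=lambda: {"DREB1": 4, "DREB2": 2, "ERF": 4, "AP2": 2,
                                 "RAV": 1, "atypical": 1}
    )
    tandem_clusters: list = field(default_factory=list)  # (chrom, n, max_gap)
    kaks_targets: list = field(default_factory=list)  # (n_codons, ks, ka)
    expression_patterns: list = field(default_factory=list)
    chromosome_length: int = 50_000_000

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.genes_per_family.values()):
            raise ValueError("gene counts must be >= 0")
        if any(c[2] <= 0 for c in self.tandem_clusters):
            raise ValueError("max_gap must be > 0")
        if any(t[1] < 0 or t[2] < 0 for t in self.kaks_targets):
            raise ValueError("target rates must be >= 0")


_FAMILY_RECIPES = {
    "AP2": dict(architecture="double-AP2", motifs=frozenset(), v14="V"),
    "RAV": dict(architecture="AP2+B3", motifs=frozenset(), v14="V"),
    "atypical": dict(architecture="single-AP2-no-WLG", motifs=frozenset(), v14="V"),
    "DREB1": dict(
        architecture="single-AP2-with-WLG",
        motifs=frozenset({"DREB1-NLS", "DSAW", "LWSY"}),
        v14="V",
    ),
    "DREB2": dict(
        architecture="single-AP2-with-WLG",
        motifs=frozenset({"DREB2-NLS", "CMIV-1"}),
        v14="V",
    ),
    "ERF": dict(architecture="single-AP2-with-WLG", motifs=frozenset(), v14="A"),
}

EXPECTED_LABELS = {
    "AP2": ("AP2", "unassigned"),
    "RAV": ("RAV", "unassigned"),
    "atypical": ("atypical", "unassigned"),
    "DREB1": ("DREB-candidate", "A-1"),
    "DREB2": ("DREB-candidate", "A-2"),
    "ERF": ("ERF", "unassigned"),
}


@dataclass
class GenomeFixture:
    proteins: list
    cds: list
    genes: list
    truth: pd.DataFrame


def make_genome_fixture(spec: FixtureSpec) -> GenomeFixture:
    """Build a synthetic family genome: per-family proteins/CDSs, a gene map
    with planted tandem clusters, and a truth table recording every planted
    label. Non-cluster genes are spaced > 200 kb apart; cluster members sit
    within their cluster's ``max_gap``.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_names = [
        f"Chr{i // 4 + 1}{'ABCD'[i % 4]}" for i in range(spec.n_chromosomes)
    ]
    cursors = {c: 100_000 for c in chrom_names}
    proteins, cds_records, genes = [], [], []
    rows = []
    counter = 0

    def place(chrom: str, length_bp: int, gap: int) -> tuple[int, int]:
        if chrom not in cursors:
            cursors[chrom] = 100_000
        start = cursors[chrom]
        end = start + length_bp - 1
        cursors[chrom] = end + gap
        if cursors[chrom] > spec.chromosome_length:
            raise ValueError(
                f"chromosome {chrom} too short to satisfy gene spacing"
            )
        return start, end

    def add_gene(family: str, chrom: str, gap: int, cluster_id: int,
                 protein: SequenceRecord | None = None):
        nonlocal counter
        counter += 1
        gid = f"g{counter:03d}"
        if protein is None:
            recipe = _FAMILY_RECIPES[family]
            protein, _ = build_protein_truth(
                recipe["architecture"], recipe["motifs"],
                seed=int(rng.integers(0, 2**31 - 1)), v14=recipe["v14"],
                record_id=f"{gid}.p",
            )
        else:
            protein = SequenceRecord(f"{gid}.p", protein.sequence, "protein")
        cds = reverse_translate(protein, rng)
        start, end = place(chrom, 3 * len(protein), gap)
        sf, sg = EXPECTED_LABELS[family]
        proteins.append(protein)
        cds_records.append(cds)
        genes.append(GeneModel(gid, chrom, start, end, "+", protein.id, cds.id))
        rows.append(
            dict(gene_id=gid, protein_id=protein.id, cds_id=cds.id,
                 chromosome=chrom, start=start, end=end, family=family,
                 superfamily=sf, subgroup=sg, cluster_id=cluster_id)
        )
        return protein

    # planted tandem clusters (copies of one DREB1-family protein each)
    for chrom, n_members, max_gap in spec.tandem_clusters:
        if n_members < 2:
            raise ValueError("a planted cluster needs >= 2 members")
        template, _ = build_protein_truth(
            "single-AP2-with-WLG", {"DREB1-NLS", "DSAW", "LWSY"},
            seed=int(rng.integers(0, 2**31 - 1)), record_id="template",
        )
        cluster_no = max((r["cluster_id"] for r in rows), default=0) + 1
        for k in range(n_members):
            lo = max(1, min(500, max_gap // 2))
            gap = int(rng.integers(lo, max_gap))  # adjacent separation < max_gap
            if k == n_members - 1:
                gap = 250_001  # separate the cluster from downstream genes
            add_gene("DREB1", chrom, gap, cluster_no, protein=template)

    # scattered singleton genes, round-robin over chromosomes
    ci = 0
    for family in sorted(spec.genes_per_family):
        for _ in range(spec.genes_per_family[family]):
            chrom = chrom_names[ci % len(chrom_names)]
            ci += 1
            add_gene(family, chrom, 250_001, 0)

    truth = pd.DataFrame(rows)
    return GenomeFixture(proteins, cds_records, genes, truth)


# ------------------------------------------------------------ codon pairs

from functools import lru_cache


@lru_cache(maxsize=None)
def _neighbors(codon: str, synonymous: bool) -> tuple[str, ...]:
    aa = translate_codon(codon)
    out = []
    for pos in range(3):
        for n in NUCS:
            if n == codon[pos]:
                continue
            alt = codon[:pos] + n + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            if (translate_codon(alt) == aa) == synonymous:
                out.append(alt)
    return tuple(out)


def mutate_cds_pair(
    n_codons: int, target_ks: float, target_ka: float, seed: int = 0
) -> tuple[str, str]:
    """A random ancestral CDS and a derived copy carrying Poisson numbers of
    synonymous and nonsynonymous single-nucleotide codon changes.

    Event counts are Poisson with means ``target_ks * S`` and
    ``target_ka * N`` (S, N = NG86 site counts of the ancestor), event
    positions weighted by each codon's current synonymous (resp.
    nonsynonymous) mutational opportunity, matching the equal-weight
    single-step model NG86 assumes — so NG86 estimates are unbiased in
    expectation. Stop codons are never introduced. Deterministic per seed.
    """
    if not (0 <= target_ks < 0.7 and 0 <= target_ka < 0.7):
        raise ValueError("target rates must lie in [0, 0.7) to avoid saturation")
    if n_codons < 1:
        raise ValueError("need at least one codon")
    rng = np.random.default_rng(seed)
    ancestor = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]

    s_sites = sum(syn_site_fraction(c) for c in ancestor)
    n_sites = 3.0 * n_codons - s_sites
    if target_ks > 0 and s_sites == 0:
        raise ValueError("no synonymous sites available for the requested Ks")
    if target_ka > 0 and n_sites == 0:
        raise ValueError("no nonsynonymous sites available for the requested Ka")

    n_syn = int(rng.poisson(target_ks * s_sites))
    n_non = int(rng.poisson(target_ka * n_sites))
    events = ["syn"] * n_syn + ["non"] * n_non
    rng.shuffle(events)

    derived = list(ancestor)
    for kind in events:
        synonymous = kind == "syn"
        weights = np.array(
            [len(_neighbors(c, synonymous)) for c in derived], dtype=float
        )
        total = weights.sum()
        if total == 0:
            raise ValueError(f"no {kind}onymous mutational opportunity left")
        idx = int(rng.choice(n_codons, p=weights / total))
        derived[idx] = rng.choice(_neighbors(derived[idx], synonymous))
    return "".join(ancestor), "".join(derived)


# ------------------------------------------------------------ alignments

def make_two_clade_alignment(
    n_per_clade: int = 3,
    n_cols: int = 100,
    split_fraction: float = 0.6,
    n_subclade: int = 10,
    n_private: int = 2,
    seed: int = 0,
) -> tuple[list[SequenceRecord], tuple[frozenset, frozenset]]:
    """An aligned protein fixture with two well-separated clades.

    A ``split_fraction`` of columns distinguishes the clades; within each
    clade the first two members share ``n_subclade`` further substitutions
    (so every internal edge carries signal); each member adds a few private
    substitutions. Returns (alignment, the true clade split)."""
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list(AMINO_ACIDS), size=n_cols))
    n_split = int(round(split_fraction * n_cols))
    split_cols = rng.choice(n_cols, size=n_split, replace=False)
    alt = list(base)
    for c in split_cols:
        alt[c] = rng.choice([a for a in AMINO_ACIDS if a != base[c]])
    clade_seqs = {"A": base, "B": "".join(alt)}
    records = []
    for clade in ("A", "B"):
        sub_cols = rng.choice(n_cols, size=n_subclade, replace=False)
        sub_res = {
            c: rng.choice([a for a in AMINO_ACIDS if a != clade_seqs[clade][c]])
            for c in sub_cols
        }
        for k in range(n_per_clade):
            seq = list(clade_seqs[clade])
            if n_per_clade >= 3 and k < 2:  # shared sub-clade signal
                for c, res in sub_res.items():
                    seq[c] = res
            priv = rng.choice(n_cols, size=n_private, replace=False)
            for c in priv:
                seq[c] = rng.choice([a for a in AMINO_ACIDS if a != seq[c]])
            records.append(
                SequenceRecord(f"{clade}{k + 1}", "".join(seq), "protein",
                               aligned=True)
            )
    split = (
        frozenset(f"A{k + 1}" for k in range(n_per_clade)),
        frozenset(f"B{k + 1}" for k in range(n_per_clade)),
    )
    return records, split


# ------------------------------------------------------------ expression

TISSUE_SAMPLES = {"leaf": ["leaf_1", "leaf_2", "leaf_3"],
                  "stalk": ["stalk_1", "stalk_2", "stalk_3"]}
GRADIENT_SAMPLES = ["zone_1", "zone_2", "zone_3", "zone_4"]
DIURNAL_SERIES = [
    (["d1_L1", "d1_L2", "d1_L3"], ["d1_D1", "d1_D2", "d1_D3"]),
    (["d2_L1", "d2_L2"], ["d2_D1", "d2_D2"]),
]
STRESS_PAIRS = {
    "drought": [("drought_t", "drought_ck")],
    "cold": [("cold_hyper_t", "cold_hyper_ck"), ("cold_hypo_t", "cold_hypo_ck")],
}

EXPRESSION_PATTERNS = (
    "undetectable",
    "constitutive",
    "leaf-preferential",
    "gradient-increasing",
    "gradient-decreasing",
    "gradient-peaked",
    "light-elevated",
    "drought-induced",
    "cold-induced-200x",
)


def _all_samples() -> list[str]:
    samples = TISSUE_SAMPLES["leaf"] + TISSUE_SAMPLES["stalk"] + GRADIENT_SAMPLES
    for light, dark in DIURNAL_SERIES:
        samples += light + dark
    for pairs in STRESS_PAIRS.values():
        for t, c in pairs:
            samples += [t, c]
    return samples


def expression_design() -> pd.DataFrame:
    rows = []
    for group, names in TISSUE_SAMPLES.items():
        rows += [dict(sample=s, analysis="tissue", group=group) for s in names]
    for pos, s in enumerate(GRADIENT_SAMPLES, start=1):
        rows.append(dict(sample=s, analysis="gradient", group="gradient", position=pos))
    for si, (light, dark) in enumerate(DIURNAL_SERIES, start=1):
        rows += [dict(sample=s, analysis="diurnal", group="diurnal",
                      series=si, phase="light") for s in light]
        rows += [dict(sample=s, analysis="diurnal", group="diurnal",
                      series=si, phase="dark") for s in dark]
    for cond, pairs in STRESS_PAIRS.items():
        for pid, (t, c) in enumerate(pairs, start=1):
            rows.append(dict(sample=t, analysis="stress", group=cond,
                             condition=cond, pair=f"{cond}{pid}", role="treated"))
            rows.append(dict(sample=c, analysis="stress", group=cond,
                             condition=cond, pair=f"{cond}{pid}", role="control"))
    return pd.DataFrame(rows).set_index("sample")


def _pattern_profile(pattern: str) -> dict[str, float]:
    prof = {s: 10.0 for s in _all_samples()}
    if pattern == "undetectable":
        prof = {s: 0.2 for s in prof}
    elif pattern == "constitutive":
        pass
    elif pattern == "leaf-preferential":
        prof.update({s: 40.0 for s in TISSUE_SAMPLES["leaf"]})
        prof.update({s: 4.0 for s in TISSUE_SAMPLES["stalk"]})
    elif pattern == "gradient-increasing":
        prof.update(dict(zip(GRADIENT_SAMPLES, [2.0, 8.0, 32.0, 128.0])))
    elif pattern == "gradient-decreasing":
        prof.update(dict(zip(GRADIENT_SAMPLES, [128.0, 32.0, 8.0, 2.0])))
    elif pattern == "gradient-peaked":
        prof.update(dict(zip(GRADIENT_SAMPLES, [5.0, 40.0, 5.0, 5.0])))
    elif pattern == "light-elevated":
        for light, dark in DIURNAL_SERIES:
            prof.update({s: 30.0 for s in light})
            prof.update({s: 5.0 for s in dark})
    elif pattern == "drought-induced":
        for t, c in STRESS_PAIRS["drought"]:
            prof[t], prof[c] = 50.0, 2.0
    elif pattern == "cold-induced-200x":
        for t, c in STRESS_PAIRS["cold"]:
            prof[t], prof[c] = 200.0, 1.0
    else:
        raise ValueError(f"unknown expression pattern {pattern!r}")
    return prof


def make_expression_fixture(
    patterns: list[str] | None = None,
    n_genes: int = 45,
    seed: int = 0,
    sigma: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """FPKM matrix (genes x samples) with planted patterns, the sample
    design table, and the truth table. Multiplicative log-normal noise of
    scale ``sigma`` is applied (``sigma=0`` gives exact template values)."""
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    patterns = list(patterns) if patterns is not None else list(EXPRESSION_PATTERNS)
    rng = np.random.default_rng(seed)
    design = expression_design()
    samples = list(design.index)
    rows, truth_rows = [], []
    for i in range(n_genes):
        pattern = patterns[i % len(patterns)]
        prof = _pattern_profile(pattern)
        noise = (
            np.exp(rng.normal(0.0, sigma, size=len(samples)))
            if sigma > 0
            else np.ones(len(samples))
        )
        rows.append([prof[s] * z for s, z in zip(samples, noise)])
        truth_rows.append(dict(gene=f"gene{i + 1:03d}", pattern=pattern))
    matrix = pd.DataFrame(
        rows, index=[r["gene"] for r in truth_rows], columns=samples
    )
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return matrix, design, truth
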