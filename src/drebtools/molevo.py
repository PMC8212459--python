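"""Codon-level molecular evolution and distance-based phylogenetics.

* Nei–Gojobori (1986) Ka/Ks counting with equal-weight pathway averaging
  and Jukes–Cantor correction, plus a Fisher exact test for selection.
* Ks-based divergence times under a strict molecular clock
  (T = Ks / (2 r), default rate r = 6.1e-9 substitutions/site/year).
* Poisson-corrected protein distances with pairwise deletion, Saitou–Nei
  neighbor joining, and bootstrap support.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from .records import PhyloNode, SequenceRecord

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "DivergenceEstimate",
    "DistanceMatrix",
    "codon_align",
    "ng86",
    "fisher_selection_test",
    "divergence_time",
    "poisson_distance",
    "nj_tree",
    "bootstrap_support",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)
NUCS = "ACGT"


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon, '*' for stop."""
    return "*" if codon in STOP_CODONS else CODON_TO_AA[codon]


# ------------------------------------------------------------ codon alignment

@dataclass(frozen=True)
class CodonAlignment:
    """A pair of frame-aligned, gapped CDS strings plus the mask of
    analyzable codon columns (no gap, N or stop in either sequence)."""

    cds_a: str
    cds_b: str
    mask: tuple[bool, ...]

    @property
    def n_codons(self) -> int:
        return len(self.cds_a) // 3

    def analyzable_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, ok in enumerate(self.mask):
            if ok:
                out.append((self.cds_a[3 * i : 3 * i + 3], self.cds_b[3 * i : 3 * i + 3]))
        return out


def _codon_ok(codon: str) -> bool:
    return (
        "-" not in codon
        and "N" not in codon
        and codon not in STOP_CODONS
    )


def pair_alignment(cds_a: str, cds_b: str) -> CodonAlignment:
    """Build a :class:`CodonAlignment` from two equal-length, frame-aligned
    CDS strings (gaps in multiples of 3 on codon boundaries)."""
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDS lengths differ")
    if len(cds_a) % 3:
        raise ValueError("aligned CDS length not divisible by 3")
    for name, s in (("first", cds_a), ("second", cds_b)):
        for i in range(0, len(s), 3):
            codon = s[i : i + 3]
            if "-" in codon and codon != "---":
                raise ValueError(
                    f"{name} sequence: gap not aligned to codon frame at "
                    f"nucleotide {i + 1}"
                )
    mask = tuple(
        _codon_ok(cds_a[i : i + 3]) and _codon_ok(cds_b[i : i + 3])
        for i in range(0, len(cds_a), 3)
    )
    return CodonAlignment(cds_a, cds_b, mask)


def codon_align(
    protein_alignment: list[SequenceRecord],
    cds_map: dict[str, str],
) -> list[SequenceRecord]:
    """Thread ungapped CDSs onto a protein alignment (pal2nal style).

    Each protein gap becomes one codon gap; every residue must translate
    from its codon under the standard code.
    """
    out = []
    for prot in protein_alignment:
        cds = cds_map[prot.id].upper()
        ungapped = prot.ungapped()
        expect = 3 * len(ungapped)
        if len(cds) not in (expect, expect + 3):  # optional trailing stop
            raise ValueError(
                f"{prot.id}: CDS length {len(cds)} does not match "
                f"3 x protein length ({expect})"
            )
        aligned = []
        k = 0
        for pos, aa in enumerate(prot.sequence, start=1):
            if aa == "-":
                aligned.append("---")
                continue
            codon = cds[3 * k : 3 * k + 3]
            trans = translate_codon(codon) if "N" not in codon else "X"
            if aa != "X" and trans != "X" and trans != aa:
                raise ValueError(
                    f"{prot.id}: residue {aa!r} at alignment column {pos} "
                    f"does not translate from codon {codon!r} ({trans!r})"
                )
            aligned.append(codon)
            k += 1
        out.append(SequenceRecord(prot.id, "".join(aligned), "dna", aligned=True))
    return out


# ------------------------------------------------------------ NG86

@lru_cache(maxsize=None)
def syn_site_fraction(codon: str) -> float:
    """NG86 synonymous-site count of one sense codon: at each position the
    fraction of the three single-nucleotide changes that are synonymous
    (changes to stop codons count as nonsynonymous)."""
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for n in NUCS:
            if n == codon[pos]:
                continue
            alt = codon[:pos] + n + codon[pos + 1 :]
            if alt not in STOP_CODONS and translate_codon(alt) == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (nonsynonymous, synonymous) substitution counts
    between two sense codons; minimal pathways through stop codons are
    excluded (all pathways used if every one is blocked)."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        current = codon_a
        nd = sd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if translate_codon(nxt) == translate_codon(current):
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            paths.append((nd, sd))
    if not paths:  # all minimal pathways pass a stop; fall back to including them
        for order in itertools.permutations(diff):
            current = codon_a
            nd = sd = 0
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                if nxt in STOP_CODONS or translate_codon(nxt) != translate_codon(current):
                    nd += 1
                else:
                    sd += 1
                current = nxt
            paths.append((nd, sd))
    nd = sum(p[0] for p in paths) / len(paths)
    sd = sum(p[1] for p in paths) / len(paths)
    return nd, sd


@dataclass(frozen=True)
class KaKsResult:
    N: float
    S: float
    Nd: float
    Sd: float
    pn: float
    ps: float
    ka: float | None
    ks: float | None
    ratio: float | None
    saturated: bool
    n_codons: int
    p_value: float | None = None


def jukes_cantor(p: float) -> float | None:
    """d = -(3/4) ln(1 - 4p/3); None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86(alignment: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks on an aligned codon pair.

    Sites are averaged over the two sequences; multi-hit codons are averaged
    over all minimal substitution pathways with equal weights.
    """
    pairs = alignment.analyzable_pairs()
    if not pairs:
        raise ValueError("no analyzable codons")
    S = N = Nd = Sd = 0.0
    for ca, cb in pairs:
        s = (syn_site_fraction(ca) + syn_site_fraction(cb)) / 2.0
        S += s
        N += 3.0 - s
        nd, sd = _pathway_counts(ca, cb)
        Nd += nd
        Sd += sd
    pn = Nd / N if N else 0.0
    ps = Sd / S if S else 0.0
    ka = jukes_cantor(pn)
    ks = jukes_cantor(ps)
    saturated = ka is None or ks is None
    ratio = None
    if not saturated and ks and ks > 0:
        ratio = ka / ks
    return KaKsResult(N, S, Nd, Sd, pn, ps, ka, ks, ratio, saturated,
                      n_codons=len(pairs))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fisher_selection_test(result: KaKsResult) -> float:
    """Two-sided Fisher exact test on the rounded 2x2 substitution table
    [[Nd, N-Nd], [Sd, S-Sd]]. An approximation: fractional counts are
    rounded half away from zero."""
    if result.saturated:
        raise ValueError("selection test undefined for saturated pairs")
    table = [
        [_round_half_away(result.Nd), _round_half_away(result.N - result.Nd)],
        [_round_half_away(result.Sd), _round_half_away(result.S - result.Sd)],
    ]
    if any(cell < 0 for row in table for cell in row):
        raise ValueError(f"negative cell in contingency table {table}")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ------------------------------------------------------------ divergence time

@dataclass(frozen=True)
class DivergenceEstimate:
    ks: float
    rate: float
    t_mya: float


DEFAULT_CLOCK_RATE = 6.1e-9  # synonymous substitutions / site / year


def divergence_time(ks: float, rate: float = DEFAULT_CLOCK_RATE) -> DivergenceEstimate:
    """T = Ks / (2 r) in million years (strict clock)."""
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    if rate <= 0:
        raise ValueError("clock rate must be positive")
    return DivergenceEstimate(ks=ks, rate=rate, t_mya=ks / (2.0 * rate) * 1e-6)


# ------------------------------------------------------------ distances

@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if any(len(row) != n for row in self.values):
            raise ValueError("distance matrix must be square")
        for i in range(n):
            if self.values[i][i] != 0.0:
                raise ValueError("diagonal must be zero")
            for j in range(n):
                if self.values[i][j] < 0:
                    raise ValueError("distances must be non-negative")
                if abs(self.values[i][j] - self.values[j][i]) > 1e-12:
                    raise ValueError("distance matrix must be symmetric")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def poisson_distance(alignment: list[SequenceRecord]) -> DistanceMatrix:
    """Poisson-corrected protein distances with pairwise deletion.

    Per pair, sites where either sequence has a gap or X are removed;
    p = differing fraction of the rest; d = -ln(1 - p). A pair with no
    comparable sites is an error; p = 1 raises as undefined.
    """
    if len(alignment) < 2:
        raise ValueError("need >= 2 aligned sequences")
    length = len(alignment[0].sequence)
    if any(len(r.sequence) != length for r in alignment):
        raise ValueError("aligned sequences must have equal length")
    labels = tuple(r.id for r in alignment)
    n = len(alignment)
    mat = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = alignment[i].sequence, alignment[j].sequence
            comparable = diff = 0
            for x, y in zip(a, b):
                if x in "-X" or y in "-X":
                    continue
                comparable += 1
                if x != y:
                    diff += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            p = diff / comparable
            if p >= 1.0:
                raise ValueError(
                    f"saturated pair {labels[i]!r}/{labels[j]!r}: p = 1"
                )
            d = -math.log(1.0 - p)
            mat[i][j] = mat[j][i] = d
    return DistanceMatrix(labels, tuple(tuple(row) for row in mat))


# ------------------------------------------------------------ neighbor joining

def nj_tree(matrix: DistanceMatrix, clamp_negative: bool = True) -> PhyloNode:
    """Saitou–Nei neighbor joining.

    Q-criterion agglomeration; ties broken by the smallest (i, j) pair
    under each node's smallest original leaf label; the final three nodes
    are resolved exactly by the three-point formulas. Negative branch
    lengths are clamped to zero unless ``clamp_negative=False``.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")

    nodes: list[PhyloNode] = [PhyloNode(name=lbl) for lbl in matrix.labels]
    keys: list[str] = list(matrix.labels)  # tie-break key: min leaf label
    D = [list(row) for row in matrix.values]

    def clamp(x: float) -> float:
        return max(x, 0.0) if clamp_negative else x

    while len(nodes) > 3:
        m = len(nodes)
        totals = [sum(row) for row in D]
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i][j] - totals[i] - totals[j]
                a, b = sorted((keys[i], keys[j]))
                cand = (q, a, b, i, j)
                if best is None or cand < best:
                    best = cand
        _q, _a, _b, i, j = best
        dij = D[i][j]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2.0 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        new = PhyloNode(children=[child_i, child_j])
        new_key = min(keys[i], keys[j])

        new_row = []
        for k in range(m):
            if k in (i, j):
                continue
            new_row.append(0.5 * (D[i][k] + D[j][k] - dij))
        keep = [k for k in range(m) if k not in (i, j)]
        D = [[D[a][b] for b in keep] for a in keep]
        for r, dist in zip(D, new_row):
            r.append(dist)
        D.append(new_row + [0.0])
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [new_key]

    # resolve the final trifurcation exactly
    (a, b, c) = nodes
    dab, dac, dbc = D[0][1], D[0][2], D[1][2]
    a.length = clamp(0.5 * (dab + dac - dbc))
    b.length = clamp(0.5 * (dab + dbc - dac))
    c.length = clamp(0.5 * (dac + dbc - dab))
    return PhyloNode(children=[a, b, c])


# ------------------------------------------------------------ bootstrap

@dataclass(frozen=True)
class BootstrapResult:
    tree: PhyloNode
    n_replicates: int
    n_skipped: int


def bootstrap_support(
    alignment: list[SequenceRecord],
    n_reps: int = 1000,
    seed: int | None = None,
) -> BootstrapResult:
    """NJ tree with bootstrap support.

    Alignment columns are resampled with replacement per replicate; each
    replicate tree is built via Poisson distance + NJ; support on each
    internal edge of the full-data tree is the percentage of replicates
    containing that bipartition. Replicates with undefined distances are
    skipped and tallied.
    """
    if not alignment or len(alignment[0].sequence) < 1:
        raise ValueError("alignment must have >= 1 column")
    full = nj_tree(poisson_distance(alignment))
    if n_reps == 0:
        return BootstrapResult(full, 0, 0)

    rng = np.random.default_rng(seed)
    length = len(alignment[0].sequence)
    counts: dict[frozenset[str], int] = {split: 0 for split in full.bipartitions()}
    skipped = 0
    used = 0
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = [
            SequenceRecord(
                r.id, "".join(r.sequence[c] for c in cols), r.alphabet, aligned=True
            )
            for r in alignment
        ]
        try:
            rep_tree = nj_tree(poisson_distance(resampled))
        except ValueError:
            skipped += 1
            continue
        used += 1
        rep_splits = rep_tree.bipartitions()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    for node in full.preorder():
        if node is full or node.is_leaf:
            continue
        all_leaves = frozenset(full.leaf_names())
        side = frozenset(node.leaf_names())
        if min(all_leaves) in side:
            side = all_leaves - side
        if side in counts and used:
            node.support = 100.0 * counts[side] / used
    return BootstrapResult(full, n_reps, skipped)
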