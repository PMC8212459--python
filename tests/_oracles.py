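"""Independent oracles used by the test suite.

Each oracle is implemented from the definition, with different code
structure (recursive enumeration rather than permutation loops) and,
where possible, different underlying libraries than the implementation
under test.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_TAB = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TAB.stop_codons)


def _aa(codon: str) -> str:
    return "*" if codon in _STOPS else _TAB.forward_table[codon]


def oracle_codon_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one sense codon by
    9-neighbor enumeration; mutations to stops count as nonsynonymous."""
    syn = 0
    for i in range(3):
        for nt in "ACGT":
            if nt == codon[i]:
                continue
            alt = codon[:i] + nt + codon[i + 1 :]
            if alt not in _STOPS and _aa(alt) == _aa(codon):
                syn += 1
    s = syn / 3.0
    return 3.0 - s, s


def _enumerate_paths(cur: str, target: str, allow_stops: bool):
    """All substitution orderings cur -> target as (nonsyn, syn) step counts,
    by recursion on the remaining differing positions."""
    diffs = [i for i in range(3) if cur[i] != target[i]]
    if not diffs:
        return [(0, 0)]
    out = []
    for i in diffs:
        nxt = cur[:i] + target[i] + cur[i + 1 :]
        if nxt in _STOPS and not allow_stops:
            continue
        step = (0, 1) if _aa(nxt) == _aa(cur) else (1, 0)
        for n, s in _enumerate_paths(nxt, target, allow_stops):
            out.append((n + step[0], s + step[1]))
    return out


def oracle_pair_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Equal-weight pathway-averaged (Nd, Sd) between two sense codons."""
    paths = _enumerate_paths(codon_a, codon_b, allow_stops=False)
    if not paths:
        paths = _enumerate_paths(codon_a, codon_b, allow_stops=True)
    nd = sum(p[0] for p in paths) / len(paths)
    sd = sum(p[1] for p in paths) / len(paths)
    return nd, sd


def oracle_ng86(cds_a: str, cds_b: str) -> tuple[float, float, float, float]:
    """(N, S, Nd, Sd) for a gap-free pair of sense-codon sequences."""
    N = S = Nd = Sd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        na, sa = oracle_codon_sites(ca)
        nb, sb = oracle_codon_sites(cb)
        N += (na + nb) / 2.0
        S += (sa + sb) / 2.0
        nd, sd = oracle_pair_counts(ca, cb)
        Nd += nd
        Sd += sd
    return N, S, Nd, Sd


SENSE_CODONS = sorted(set(_TAB.forward_table))


def random_codon_pair(rng: np.random.Generator, n_codons: int) -> tuple[str, str]:
    """Two independent random sense-codon sequences of equal length."""
    a = "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons))
    b = "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons))
    return a, b


# ---------------------------------------------------------------- trees

def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """A random binary tree with branch lengths in [0.1, 1.1]; returns
    (leaf labels, pairwise path-distance matrix, set of non-trivial splits).
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    # each node: (leaf_set, {leaf: distance to this node})
    nodes = [(frozenset([lbl]), {lbl: 0.0}) for lbl in labels]
    splits = set()
    dist = {}

    def join(a, b):
        la = 0.1 + rng.random()
        lb = 0.1 + rng.random()
        set_a, da = a
        set_b, db = b
        for x, dx in da.items():
            for y, dy in db.items():
                dist[frozenset((x, y))] = dx + la + dy + lb
        merged = set_a | set_b
        dmap = {x: d + la for x, d in da.items()}
        dmap.update({y: d + lb for y, d in db.items()})
        return merged, dmap

    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = join(nodes[i], nodes[j])
        for side in (nodes[i][0], nodes[j][0], merged[0]):
            if 1 < len(side) < n_taxa - 1:
                splits.add(frozenset(side))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [merged]
    # connect the last two with a single edge
    set_a, da = nodes[0]
    set_b, db = nodes[1]
    edge = 0.1 + rng.random()
    for x, dx in da.items():
        for y, dy in db.items():
            dist[frozenset((x, y))] = dx + edge + dy
    for side in (set_a, set_b):
        if 1 < len(side) < n_taxa - 1:
            splits.add(frozenset(side))

    n = len(labels)
    matrix = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[frozenset((labels[i], labels[j]))]
            matrix[i][j] = matrix[j][i] = d
    anchor = min(labels)
    all_set = frozenset(labels)
    canon = {s if anchor not in s else all_set - s for s in splits}
    canon = {s for s in canon if 1 < len(s) < n - 1}
    return labels, matrix, canon


def patristic_distances(tree) -> dict[frozenset, float]:
    """Leaf-to-leaf path distances of a PhyloNode tree."""
    out: dict[frozenset, float] = {}

    def walk(node):
        if node.is_leaf:
            return {node.name: 0.0}
        maps = [walk(c) for c in node.children]
        for i in range(len(maps)):
            for j in range(i + 1, len(maps)):
                li = node.children[i].length or 0.0
                lj = node.children[j].length or 0.0
                for x, dx in maps[i].items():
                    for y, dy in maps[j].items():
                        out[frozenset((x, y))] = dx + li + dy + lj
        merged = {}
        for child, m in zip(node.children, maps):
            for x, d in m.items():
                merged[x] = d + (child.length or 0.0)
        return merged

    walk(tree)
    return out
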