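"""Degenerate consensus motifs diagnostic for DREB subgroups, and the
AP2/B3 domain consensus cores used by the synthetic generator and the
sequence-based (no-HMM-table) domain detector.

A motif is an ordered list of per-position residue sets; ``x`` means any
residue. Matching is exact set membership with no mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import PROTEIN_ALPHABET, SequenceRecord

_FULL = frozenset(PROTEIN_ALPHABET)


@dataclass(frozen=True)
class MotifPattern:
    name: str
    positions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.positions) < 3:
            raise ValueError(f"motif {self.name!r}: length must be >= 3")
        if any(not p for p in self.positions):
            raise ValueError(f"motif {self.name!r}: empty position set")

    def __len__(self) -> int:
        return len(self.positions)


def pattern(name: str, spec: str) -> MotifPattern:
    """Build a pattern from a compact string: plain residues, ``x`` for any,
    ``[KR]`` for alternatives."""
    sets: list[frozenset[str]] = []
    i = 0
    while i < len(spec):
        ch = spec[i]
        if ch == "[":
            j = spec.index("]", i)
            sets.append(frozenset(spec[i + 1 : j]))
            i = j + 1
        elif ch == "x":
            sets.append(_FULL)
            i += 1
        else:
            sets.append(frozenset(ch))
            i += 1
    return MotifPattern(name, tuple(sets))


# -------------------------------------------------------- named motifs
# The two canonical DREB subgroups are diagnosed by the motif context of the
# AP2/ERF domain: an upstream basic NLS plus flanking DSAW/LWSY motifs for
# the DREB1 type, and an upstream [K/R]GKGGPxN (CMIV-1) core — usually inside
# a longer PKK-like NLS — for the DREB2 type. Position 8 of the DREB1 NLS is
# reported both as T/K and as unconstrained; the T/K reading is the default
# and `dreb1_nls_pattern(strict_pos8=False)` relaxes it.

WLG = pattern("WLG", "WLG")
DSAW = pattern("DSAW", "DSAW")
LWSY = pattern("LWSY", "LWSY")
CMIV1 = pattern("CMIV-1", "[KR]GKGGPxN")
DREB2_NLS = pattern("DREB2-NLS", "RKxPAKGSKKGCMxGKGGPENxx")


def dreb1_nls_pattern(strict_pos8: bool = True) -> MotifPattern:
    pos8 = "[TK]" if strict_pos8 else "x"
    return pattern("DREB1-NLS", f"[PK]K[RK][PR][AT]GR{pos8}KFRETRHP")


DREB1_NLS = dreb1_nls_pattern()

NAMED_MOTIFS: dict[str, MotifPattern] = {
    "WLG": WLG,
    "DSAW": DSAW,
    "LWSY": LWSY,
    "CMIV-1": CMIV1,
    "DREB1-NLS": DREB1_NLS,
    "DREB2-NLS": DREB2_NLS,
}


# -------------------------------------------------------- scanning

def scan_motif(protein: SequenceRecord | str, motif: MotifPattern) -> list[tuple[int, int]]:
    """All non-overlapping leftmost matches of ``motif`` in an ungapped
    protein. Returns 1-based inclusive (start, end) pairs; empty list when
    absent."""
    seq = protein.sequence if isinstance(protein, SequenceRecord) else protein
    if "-" in seq:
        raise ValueError("scan_motif requires an ungapped protein")
    m = len(motif)
    matches: list[tuple[int, int]] = []
    i = 0
    while i + m <= len(seq):
        if all(seq[i + k] in motif.positions[k] for k in range(m)):
            matches.append((i + 1, i + m))
            i += m
        else:
            i += 1
    return matches


# -------------------------------------------------------- domain cores
# Synthetic 60-residue AP2/ERF representative cores. These are in-package
# constructions (not database sequences): a shared scaffold carrying the
# diagnostic coordinates — position 14 (V in DREB/A in ERF), position 19 (E),
# the WLG tripeptide at 29-31 — and subfamily-distinct C-terminal tails so
# that similarity against the two cores can break ties when residue 14 is
# neither V nor A.

_SEG1 = "SGIRYRGVRQRPW"  # positions 1-13
_SEG2 = "GKFA"           # positions 15-18
_SEG3 = "IRDPAKNGA"      # positions 20-28
_DREB_TAIL = "TYETAEEAALAYDRAAFRMRGSRALLNFP"  # positions 32-60
_ERF_TAIL = "TFDTAHEAARAYDAEARRIRGKKAKVNFP"


def build_ap2_core(v14: str = "V", e19: str = "E", wlg: bool = True,
                   flavor: str = "dreb") -> str:
    """Assemble a 60-aa AP2/ERF core with the requested diagnostic residues."""
    tail = _DREB_TAIL if flavor == "dreb" else _ERF_TAIL
    core = _SEG1 + v14 + _SEG2 + e19 + _SEG3 + ("WLG" if wlg else "AAA") + tail
    assert len(core) == 60
    return core


DREB_DOMAIN_CONSENSUS = build_ap2_core("V", "E", True, "dreb")
ERF_DOMAIN_CONSENSUS = build_ap2_core("A", "E", True, "erf")

# Synthetic 50-aa B3 representative core (fully invariant).
B3_CORE = "REVDLNLAPSEDSFYVLPLKEGDARILHGGWRSFVRAHDLRAGDFLVFRK"
assert len(B3_CORE) == 50

# Detector pattern: invariant scaffold positions anchored, the diagnostic
# slots (14, 19, 29-31) and the divergent tail wildcarded.
_tail_union = "".join(
    f"[{d}{e}]" if d != e else d for d, e in zip(_DREB_TAIL, _ERF_TAIL)
)
AP2_CORE_PATTERN = pattern(
    "AP2-core", _SEG1 + "x" + _SEG2 + "x" + _SEG3 + "xxx" + _tail_union
)
B3_CORE_PATTERN = pattern("B3-core", B3_CORE)


def find_domains_by_consensus(protein: SequenceRecord) -> list:
    """Locate planted AP2/B3 cores by consensus scanning.

    A fallback for inputs that come without an HMM hit table (e.g. the
    synthetic genome); returns :class:`~drebtools.records.DomainHit` rows
    with the same coordinate convention as the domtblout reader.
    """
    from .records import DomainHit

    hits = [
        DomainHit(protein.id, "AP2", s, e)
        for s, e in scan_motif(protein, AP2_CORE_PATTERN)
    ]
    hits += [
        DomainHit(protein.id, "B3", s, e)
        for s, e in scan_motif(protein, B3_CORE_PATTERN)
    ]
    return sorted(hits, key=lambda h: h.start)
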