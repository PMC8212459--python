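"""ProtParam-style physicochemical profiling of protein sequences.

Implements the standard ExPASy quantities: average molecular weight,
theoretical pI (bisection on net charge with the Bjellqvist pKa set),
Kyte–Doolittle GRAVY, Ikai aliphatic index and the Guruprasad instability
index. Constant tables are taken from Biopython's data modules; the
formulas are implemented here.

Unknown residues (X): skipped (with length renormalisation) for MW, GRAVY
and AI; an error for pI and the instability index, whose dipeptide/charge
models have no defined X contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils import IsoelectricPoint as _ip
from Bio.SeqUtils.ProtParamData import DIWV, kd

from .records import SequenceRecord

WATER = 18.0153
# Average residue masses = free-amino-acid average weights minus one water.
RESIDUE_MASS = {aa: w - WATER for aa, w in protein_weights.items()}


@dataclass(frozen=True)
class PhyschemProfile:
    length_aa: int
    mw: float  # Da
    pi: float  # pH units
    gravy: float
    aliphatic_index: float
    instability_index: float

    def __post_init__(self) -> None:
        if self.length_aa < 1 or self.mw <= 0 or not (0 < self.pi < 14):
            raise ValueError("invalid physicochemical profile")


def molecular_weight(seq: str) -> float:
    known = [c for c in seq if c != "X"]
    return sum(RESIDUE_MASS[c] for c in known) + WATER


def gravy(seq: str) -> float:
    known = [c for c in seq if c != "X"]
    if not known:
        raise ValueError("GRAVY undefined: no known residues")
    return sum(kd[c] for c in known) / len(known)


def aliphatic_index(seq: str) -> float:
    """AI = fA + 2.9 fV + 3.9 (fI + fL), f in mole percent (Ikai 1980)."""
    known = [c for c in seq if c != "X"]
    n = len(known)
    if n == 0:
        raise ValueError("aliphatic index undefined: no known residues")
    f = lambda aa: 100.0 * known.count(aa) / n
    return f("A") + 2.9 * f("V") + 3.9 * (f("I") + f("L"))


def instability_index(seq: str) -> float:
    """II = (10/L) * sum of Guruprasad dipeptide weights."""
    if "X" in seq:
        raise ValueError("instability index undefined for sequences with X")
    if len(seq) < 2:
        raise ValueError("instability index needs length >= 2")
    total = sum(DIWV[a][b] for a, b in zip(seq, seq[1:]))
    return 10.0 / len(seq) * total


def _net_charge(seq: str, ph: float) -> float:
    pos = dict(_ip.positive_pKs)
    neg = dict(_ip.negative_pKs)
    pos["Nterm"] = _ip.pKnterminal.get(seq[0], pos["Nterm"])
    neg["Cterm"] = _ip.pKcterminal.get(seq[-1], neg["Cterm"])
    charge = 1.0 / (1.0 + 10 ** (ph - pos["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (neg["Cterm"] - ph))
    for aa in ("K", "R", "H"):
        charge += seq.count(aa) / (1.0 + 10 ** (ph - pos[aa]))
    for aa in ("D", "E", "C", "Y"):
        charge -= seq.count(aa) / (1.0 + 10 ** (neg[aa] - ph))
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """Solve net_charge(pH) = 0 by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so the root is unique.
    """
    if "X" in seq:
        raise ValueError("pI undefined for sequences with X")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if _net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def physchem(protein: SequenceRecord | str) -> PhyschemProfile:
    """Full physicochemical profile of an ungapped protein."""
    seq = protein.sequence if isinstance(protein, SequenceRecord) else protein
    if not seq:
        raise ValueError("empty sequence")
    if "-" in seq:
        raise ValueError("physchem requires an ungapped protein")
    return PhyschemProfile(
        length_aa=len(seq),
        mw=molecular_weight(seq),
        pi=isoelectric_point(seq),
        gravy=gravy(seq),
        aliphatic_index=aliphatic_index(seq),
        instability_index=instability_index(seq),
    )
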