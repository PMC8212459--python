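"""Motif scanning, the superfamily decision tree, subgroup diagnostics,
allele grouping and chromosomal-order naming."""

import numpy as np
import pytest

from drebtools.classify import (
    assign_names,
    check_v14_e19,
    classify_superfamily,
    group_alleles,
    subgroup_dreb,
)
from drebtools.motifs import (
    CMIV1,
    NAMED_MOTIFS,
    build_ap2_core,
    dreb1_nls_pattern,
    find_domains_by_consensus,
    pattern,
    scan_motif,
)
from drebtools.records import DomainHit, GeneModel, SequenceRecord
from drebtools.synthetic import build_protein_truth

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------- motifs

def test_cmiv1_exact_set_membership():
    assert scan_motif("KGKGGPAN", CMIV1) == [(1, 8)]
    assert scan_motif("QGKGGPAN", CMIV1) == []  # first position fails


def test_scan_finds_planted_nls_at_planted_offset():
    rec, truth = build_protein_truth(
        "single-AP2-with-WLG", {"DREB1-NLS", "DSAW", "LWSY"}, seed=7
    )
    matches = scan_motif(rec, NAMED_MOTIFS["DREB1-NLS"])
    assert truth["DREB1-NLS"] in matches


def test_nls_position8_configurable():
    relaxed = dreb1_nls_pattern(strict_pos8=False)
    seq = "PKRPAGRQKFRETRHP"  # Q at position 8
    assert scan_motif(seq, relaxed) == [(1, 16)]
    assert scan_motif(seq, dreb1_nls_pattern(strict_pos8=True)) == []


def test_scan_motif_nonoverlapping_leftmost():
    assert scan_motif("DSAWDSAWDSAW", NAMED_MOTIFS["DSAW"]) == [
        (1, 4), (5, 8), (9, 12)
    ]


def test_pattern_validation():
    with pytest.raises(ValueError):
        pattern("too-short", "AB")


# ------------------------------------------------------- decision tree

def _protein_of(architecture, motifs=frozenset(), seed=0, **kw):
    rec, _ = build_protein_truth(architecture, motifs, seed, **kw)
    return rec


def test_two_ap2_hits_give_ap2_subfamily():
    rec = _protein_of("double-AP2")
    cg = classify_superfamily(rec, find_domains_by_consensus(rec))
    assert cg.superfamily == "AP2" and cg.n_ap2_domains == 2


def test_ap2_plus_b3_gives_rav():
    rec = _protein_of("AP2+B3")
    cg = classify_superfamily(rec, find_domains_by_consensus(rec))
    assert cg.superfamily == "RAV" and cg.has_b3


def test_single_domain_without_wlg_is_atypical():
    rec = _protein_of("single-AP2-no-WLG")
    cg = classify_superfamily(rec, find_domains_by_consensus(rec))
    assert cg.superfamily == "atypical"


def test_v14_discriminates_dreb_from_erf():
    dreb = _protein_of("single-AP2-with-WLG", v14="V")
    erf = _protein_of("single-AP2-with-WLG", v14="A")
    assert classify_superfamily(
        dreb, find_domains_by_consensus(dreb)
    ).superfamily == "DREB-candidate"
    assert classify_superfamily(
        erf, find_domains_by_consensus(erf)
    ).superfamily == "ERF"


def test_consensus_similarity_fallback_when_v14_ambiguous():
    # leucine at 14: neither V nor A; tails decide via similarity
    dreb_like = _protein_of("single-AP2-with-WLG", v14="L")
    cg = classify_superfamily(dreb_like, find_domains_by_consensus(dreb_like))
    assert cg.superfamily == "DREB-candidate"


def test_no_ap2_hit_is_an_error():
    rec = SequenceRecord("p1", "MKVLW" * 10)
    with pytest.raises(ValueError, match="not an AP2/ERF"):
        classify_superfamily(rec, [])


def test_foreign_hits_rejected():
    rec = _protein_of("single-AP2-with-WLG")
    hits = [DomainHit("other", "AP2", 1, 60)]
    with pytest.raises(ValueError, match="foreign"):
        classify_superfamily(rec, hits)


def test_v14_e19_positional_read():
    seq = "X" * 13 + "V" + "XXXX" + "E" + "X" * 10
    rec = SequenceRecord("p", seq)
    hit = DomainHit("p", "AP2", 1, len(seq))
    assert check_v14_e19(rec, hit) == ("V", "E")


def test_v14_e19_nonglutamate_at_19_still_read():
    # DREB1-style domains tolerate a non-E residue at position 19
    core = build_ap2_core(v14="V", e19="Q")
    rec = SequenceRecord("p", core)
    v14, e19 = check_v14_e19(rec, DomainHit("p", "AP2", 1, 60))
    assert (v14, e19) == ("V", "Q")


def test_v14_e19_short_domain_errors():
    rec = SequenceRecord("p", "MKVLWMKVLW")
    with pytest.raises(ValueError, match="< 19"):
        check_v14_e19(rec, DomainHit("p", "AP2", 1, 10))


# ------------------------------------------------------- subgroups

def _classified(motifs, seed=0):
    rec, _ = build_protein_truth("single-AP2-with-WLG", motifs, seed)
    cg = classify_superfamily(rec, find_domains_by_consensus(rec))
    return subgroup_dreb(cg, rec), rec


def test_dreb1_motif_suite_gives_a1():
    cg, _ = _classified({"DREB1-NLS", "DSAW", "LWSY"})
    assert cg.subgroup == "A-1"
    assert cg.flags["dreb1_nls"] and cg.flags["dsaw"] and cg.flags["lwsy"]


def test_cmiv1_without_pkk_nls_gives_a2():
    cg, _ = _classified({"CMIV-1"})
    assert cg.subgroup == "A-2"
    assert cg.flags["cmiv1"] and not cg.flags["dreb2_nls"]


def test_full_dreb2_nls_gives_a2_with_flag():
    cg, _ = _classified({"DREB2-NLS", "CMIV-1"})
    assert cg.subgroup == "A-2" and cg.flags["dreb2_nls"]


def test_no_upstream_motif_unassigned():
    cg, _ = _classified(frozenset())
    assert cg.subgroup == "unassigned"


def test_conflicting_upstream_evidence_is_ambiguity_error():
    rec, _ = build_protein_truth("single-AP2-with-WLG", {"DREB1-NLS"}, seed=1)
    # splice a CMIV-1 core just before the planted NLS context
    dom_start = scan_motif(rec, NAMED_MOTIFS["DREB1-NLS"])[0][0]
    seq = rec.sequence
    spliced = seq[: dom_start - 9] + "KGKGGPAN" + seq[dom_start - 1 :]
    hacked = SequenceRecord("p", spliced)
    cg = classify_superfamily(hacked, find_domains_by_consensus(hacked))
    with pytest.raises(ValueError, match="ambiguous"):
        subgroup_dreb(cg, hacked)


def test_classification_invariant_under_id_renaming():
    rec, _ = build_protein_truth(
        "single-AP2-with-WLG", {"DREB1-NLS", "DSAW", "LWSY"}, seed=11
    )
    renamed = SequenceRecord("zzz", rec.sequence)
    a = subgroup_dreb(
        classify_superfamily(rec, find_domains_by_consensus(rec)), rec
    )
    b = subgroup_dreb(
        classify_superfamily(renamed, find_domains_by_consensus(renamed)), renamed
    )
    assert (a.superfamily, a.subgroup, a.flags) == (b.superfamily, b.subgroup, b.flags)


# ------------------------------------------------------- alleles & names

def _gene(gid, chrom, start, plen=0):
    return GeneModel(gid, chrom, start, start + 999, "+", protein_id=f"{gid}.p")


def test_identical_proteins_on_homologous_chromosomes_are_one_locus(rng):
    seq = "".join(rng.choice(list(AA20), size=100))
    genes = [_gene("g1", "Chr2A", 1000), _gene("g2", "Chr2B", 5000)]
    proteins = {"g1.p": SequenceRecord("g1.p", seq),
                "g2.p": SequenceRecord("g2.p", seq)}
    loci = group_alleles(genes, proteins)
    assert len(loci) == 1 and len(loci[0]) == 2


def test_divergent_proteins_stay_separate_loci(rng):
    seq = list(rng.choice(list(AA20), size=100))
    other = list(seq)
    for i in rng.choice(100, size=40, replace=False):
        other[i] = next(a for a in AA20 if a != other[i])
    genes = [_gene("g1", "Chr2A", 1000), _gene("g2", "Chr2B", 5000)]
    proteins = {"g1.p": SequenceRecord("g1.p", "".join(seq)),
                "g2.p": SequenceRecord("g2.p", "".join(other))}
    assert len(group_alleles(genes, proteins)) == 2


def test_same_haplotype_near_identical_warns_and_splits(rng):
    seq = "".join(rng.choice(list(AA20), size=100))
    genes = [_gene("g1", "Chr2A", 1000), _gene("g2", "Chr2A", 900_000)]
    proteins = {g.protein_id: SequenceRecord(g.protein_id, seq) for g in genes}
    with pytest.warns(UserWarning, match="same haplotype"):
        loci = group_alleles(genes, proteins)
    assert len(loci) == 2


def test_single_gene_single_locus():
    genes = [_gene("g1", "Chr1A", 1000)]
    proteins = {"g1.p": SequenceRecord("g1.p", "MKVLW" * 10)}
    loci = group_alleles(genes, proteins)
    assert loci == [[genes[0]]]


def test_assign_names_orders_loci_and_alleles():
    loci = [
        [_gene("b", "Chr1A", 500_000)],
        [_gene("a1", "Chr1A", 100_000), _gene("a2", "Chr1B", 90_000)],
    ]
    names = assign_names(loci, prefix="SsDREB1")
    assert names["a1"] == "SsDREB1A-1"
    assert names["a2"] == "SsDREB1A-2"
    assert names["b"] == "SsDREB1B"


def test_assign_names_four_alleles_suffixed():
    locus = [_gene(f"g{i}", f"Chr2{h}", 1000 * i) for i, h in
             enumerate("ABCD", start=1)]
    names = assign_names([locus])
    assert sorted(names.values()) == [
        "SsDREB1A-1", "SsDREB1A-2", "SsDREB1A-3", "SsDREB1A-4"
    ]


def test_assign_names_invariant_to_input_order(rng):
    loci = [
        [_gene("x", "Chr3A", 200_000)],
        [_gene("y", "Chr1A", 700_000)],
        [_gene("z", "Chr1A", 100_000)],
    ]
    names = assign_names(loci)
    shuffled = assign_names(loci[::-1])
    assert names == shuffled
    assert names["z"] == "SsDREB1A" and names["y"] == "SsDREB1B"


def test_assign_names_overflow():
    loci = [[_gene(f"g{i}", "Chr1A", 10_000 * (i + 1))] for i in range(27)]
    with pytest.raises(ValueError, match="single-letter"):
        assign_names(loci)
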