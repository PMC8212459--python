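"""Ka/Ks counting, divergence times, distances, NJ and bootstrap."""

import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from _oracles import (
    oracle_ng86,
    patristic_distances,
    random_additive_tree,
    random_codon_pair,
)
from drebtools.io import write_newick
from drebtools.molevo import (
    DistanceMatrix,
    KaKsResult,
    bootstrap_support,
    codon_align,
    divergence_time,
    fisher_selection_test,
    ng86,
    nj_tree,
    pair_alignment,
    poisson_distance,
)
from drebtools.records import SequenceRecord
from drebtools.synthetic import make_two_clade_alignment


# ------------------------------------------------------- codon threading

def test_codon_align_threads_gaps():
    prots = [SequenceRecord("a", "MK-V", aligned=True),
             SequenceRecord("b", "MKLV", aligned=True)]
    cds = {"a": "ATGAAAGTT", "b": "ATGAAACTTGTT"}
    aligned = codon_align(prots, cds)
    assert aligned[0].sequence == "ATGAAA---GTT"
    assert aligned[1].sequence == "ATGAAACTTGTT"


def test_codon_align_translation_mismatch_names_position():
    prots = [SequenceRecord("a", "MV", aligned=True)]
    with pytest.raises(ValueError, match="column 1"):
        codon_align(prots, {"a": "GGGGTT"})


def test_codon_align_length_mismatch():
    prots = [SequenceRecord("a", "MV", aligned=True)]
    with pytest.raises(ValueError, match="length"):
        codon_align(prots, {"a": "ATGGT"})


def test_codon_align_round_trip_random(rng):
    from drebtools.synthetic import AMINO_ACIDS, reverse_translate

    for _ in range(10):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=30))
        prot = SequenceRecord("p", seq, aligned=True)
        cds = reverse_translate(SequenceRecord("p", seq), rng)
        (back,) = codon_align([prot], {"p": cds.sequence})
        assert back.sequence == cds.sequence


# ------------------------------------------------------- NG86

def test_ng86_identical_sequences():
    res = ng86(pair_alignment("ATGGTT", "ATGGTT"))
    assert res.ka == res.ks == 0.0 and res.Nd == res.Sd == 0.0


def test_ng86_single_nonsynonymous_change_hand_enumeration():
    """10 glycine codons, one G->A first-position change (GGG->AGG, Arg).

    GGG has exactly one synonymous site (the third position); the GGG/AGG
    codon pair averages to 5/6 synonymous sites because AGG adds a CGG
    (Arg) synonymous first-position neighbour. Verified against the
    exhaustive oracle.
    """
    a, b = "GGG" * 10, "AGG" + "GGG" * 9
    res = ng86(pair_alignment(a, b))
    assert res.Nd == pytest.approx(1.0, abs=1e-12)
    assert res.Sd == pytest.approx(0.0, abs=1e-12)
    assert res.S == pytest.approx(9 + 5 / 6, abs=1e-9)
    assert res.N == pytest.approx(30 - (9 + 5 / 6), abs=1e-9)
    assert res.ks == 0.0
    assert res.ka == pytest.approx(
        -0.75 * math.log(1 - 4 * res.pn / 3), abs=1e-12
    )
    oN, oS, oNd, oSd = oracle_ng86(a, b)
    assert (res.N, res.S, res.Nd, res.Sd) == pytest.approx((oN, oS, oNd, oSd))


def test_ng86_matches_exhaustive_pathway_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(1, 7))
        a, b = random_codon_pair(rng, n)
        res = ng86(pair_alignment(a, b))
        oN, oS, oNd, oSd = oracle_ng86(a, b)
        assert res.N == pytest.approx(oN, abs=1e-9)
        assert res.S == pytest.approx(oS, abs=1e-9)
        assert res.Nd == pytest.approx(oNd, abs=1e-9)
        assert res.Sd == pytest.approx(oSd, abs=1e-9)


def test_ng86_site_conservation_and_bounds(rng):
    """N + S always equals 3 x codons; substitution counts stay within the
    site counts for moderately diverged pairs (past saturation, pathway-
    averaged Sd can exceed S, which the estimator flags as saturated)."""
    from drebtools.synthetic import mutate_cds_pair

    for seed in range(10):
        a, b = random_codon_pair(rng, int(rng.integers(5, 40)))
        res = ng86(pair_alignment(a, b))
        assert res.N + res.S == pytest.approx(3 * res.n_codons, abs=1e-6)
    for seed in range(10):
        a, b = mutate_cds_pair(60, 0.25, 0.15, seed=seed)
        res = ng86(pair_alignment(a, b))
        assert res.N + res.S == pytest.approx(3 * res.n_codons, abs=1e-6)
        assert 0 <= res.Nd <= res.N and 0 <= res.Sd <= res.S
        assert not res.saturated


def test_ng86_masks_gap_and_n_codons():
    res = ng86(pair_alignment("ATG---GTTNTT", "ATGAAAGTTTTT"))
    assert res.n_codons == 2  # ATG/ATG and GTT/GTT


def test_ng86_no_analyzable_codons():
    with pytest.raises(ValueError, match="analyzable"):
        ng86(pair_alignment("---", "ATG"))


def test_pair_alignment_frame_validation():
    with pytest.raises(ValueError, match="frame"):
        pair_alignment("A--TGG", "ATGTGG")
    with pytest.raises(ValueError, match="divisible"):
        pair_alignment("ATGG", "ATGG")


# ------------------------------------------------------- Fisher test

def _result(N, S, Nd, Sd):
    return KaKsResult(N, S, Nd, Sd, Nd / N, Sd / S, 0.0, 0.0, None, False, 1)


def test_fisher_no_substitutions_p1():
    assert fisher_selection_test(_result(100, 50, 0, 0)) == 1.0


def test_fisher_matches_hypergeometric_enumeration():
    from scipy.stats import hypergeom

    res = _result(100, 100, 10, 0)
    p = fisher_selection_test(res)
    # two-sided: sum of all tables with probability <= the observed one
    rv = hypergeom(200, 10, 100)  # population, successes, draws
    probs = [rv.pmf(k) for k in range(11)]
    expected = sum(pk for pk in probs if pk <= probs[10] + 1e-12)
    assert p == pytest.approx(expected, rel=1e-6)


def test_fisher_identical_margins_p1():
    assert fisher_selection_test(_result(100, 100, 5, 5)) == pytest.approx(1.0)


def test_fisher_saturated_rejected():
    sat = KaKsResult(10, 5, 9, 4, 0.9, 0.8, None, None, None, True, 5)
    with pytest.raises(ValueError, match="saturated"):
        fisher_selection_test(sat)


# ------------------------------------------------------- divergence time

def test_divergence_time_exact_values():
    assert divergence_time(0.0).t_mya == 0.0
    assert divergence_time(0.122).t_mya == pytest.approx(10.0, rel=1e-12)


def test_divergence_time_linearity(rng):
    for _ in range(10):
        ks = float(rng.uniform(0.01, 1.0))
        c = float(rng.uniform(0.5, 3.0))
        assert divergence_time(c * ks).t_mya == pytest.approx(
            c * divergence_time(ks).t_mya, rel=1e-12
        )
        assert divergence_time(ks, rate=c * 6.1e-9).t_mya == pytest.approx(
            divergence_time(ks).t_mya / c, rel=1e-12
        )


def test_divergence_time_rejects_negative():
    with pytest.raises(ValueError):
        divergence_time(-0.1)


# ------------------------------------------------------- distances

def test_poisson_distance_closed_form():
    aln = [SequenceRecord("a", "AAAAAAAAAA", aligned=True),
           SequenceRecord("b", "AAAAAAAAAC", aligned=True)]
    d = poisson_distance(aln)
    assert d.values[0][1] == pytest.approx(-math.log(0.9), abs=1e-12)


def test_poisson_distance_identical_zero():
    aln = [SequenceRecord("a", "MKVLW", aligned=True),
           SequenceRecord("b", "MKVLW", aligned=True)]
    assert poisson_distance(aln).values[0][1] == 0.0


def test_poisson_pairwise_deletion_three_sequence_toy():
    # gaps are removed per pair, not globally
    aln = [SequenceRecord("a", "AAAAA-AAAA", aligned=True),
           SequenceRecord("b", "AAAAACAAAC", aligned=True),
           SequenceRecord("c", "-AAAACAAAA", aligned=True)]
    d = poisson_distance(aln)
    # a vs b: 9 comparable, 1 diff; a vs c: 8 comparable, 0 diff
    # b vs c: 9 comparable, 1 diff
    assert d.values[0][1] == pytest.approx(-math.log(1 - 1 / 9))
    assert d.values[0][2] == 0.0
    assert d.values[1][2] == pytest.approx(-math.log(1 - 1 / 9))


def test_poisson_distance_no_comparable_sites():
    aln = [SequenceRecord("a", "A--", aligned=True),
           SequenceRecord("b", "-AA", aligned=True)]
    with pytest.raises(ValueError, match="comparable"):
        poisson_distance(aln)


def test_poisson_distance_saturated_pair():
    aln = [SequenceRecord("a", "AAAA", aligned=True),
           SequenceRecord("b", "CCCC", aligned=True)]
    with pytest.raises(ValueError, match="p = 1"):
        poisson_distance(aln)


# ------------------------------------------------------- neighbor joining

def test_nj_four_taxon_additive_exact():
    # tree ((A:1,B:2):1,(C:3,D:1)) -> additive distances
    labels = ("A", "B", "C", "D")
    d = {
        ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 3,
        ("B", "C"): 6, ("B", "D"): 4, ("C", "D"): 4,
    }
    mat = [[0.0] * 4 for _ in range(4)]
    for (x, y), v in d.items():
        i, j = labels.index(x), labels.index(y)
        mat[i][j] = mat[j][i] = float(v)
    tree = nj_tree(DistanceMatrix(labels, tuple(map(tuple, mat))))
    assert tree.bipartitions() == {frozenset({"C", "D"})}
    pat = patristic_distances(tree)
    for (x, y), v in d.items():
        assert pat[frozenset((x, y))] == pytest.approx(v, abs=1e-9)


def test_nj_three_taxa_star_three_point_lengths():
    mat = ((0.0, 2.0, 3.0), (2.0, 0.0, 4.0), (3.0, 4.0, 0.0))
    tree = nj_tree(DistanceMatrix(("A", "B", "C"), mat))
    lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
    assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})


def test_nj_rejects_fewer_than_three():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(("A", "B"), ((0.0, 1.0), (1.0, 0.0))))


def test_nj_recovers_random_additive_trees(rng):
    for _ in range(50):
        n = int(rng.integers(4, 9))
        labels, mat, true_splits = random_additive_tree(rng, n)
        tree = nj_tree(DistanceMatrix(tuple(labels), tuple(map(tuple, mat))))
        assert tree.bipartitions() == true_splits  # RF distance 0
        pat = patristic_distances(tree)
        for i in range(n):
            for j in range(i + 1, n):
                assert pat[frozenset((labels[i], labels[j]))] == pytest.approx(
                    mat[i][j], abs=1e-9
                )


def test_nj_topology_agrees_with_dendropy(rng):
    import io as _io

    for seed in range(5):
        local = np.random.default_rng(seed)
        labels, mat, _ = random_additive_tree(local, 7)
        ours = nj_tree(DistanceMatrix(tuple(labels), tuple(map(tuple, mat))))
        csv = "x," + ",".join(labels) + "\n" + "\n".join(
            labels[i] + "," + ",".join(str(v) for v in mat[i])
            for i in range(len(labels))
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_io.StringIO(csv), delimiter=","
        )
        ref = pdm.nj_tree()
        tns = ref.taxon_namespace
        mine = dendropy.Tree.get(
            data=write_newick(ours), schema="newick", taxon_namespace=tns
        )
        ref.encode_bipartitions()
        mine.encode_bipartitions()
        assert treecompare.symmetric_difference(ref, mine) == 0


# ------------------------------------------------------- bootstrap

def test_bootstrap_strong_signal_high_support():
    aln, (clade_a, clade_b) = make_two_clade_alignment(seed=3)
    res = bootstrap_support(aln, n_reps=300, seed=7)
    supports = [n.support for n in res.tree.preorder() if n.support is not None]
    assert supports and min(supports) >= 95.0
    assert res.n_skipped == 0
    split_supports = {
        frozenset(n.leaf_names()): n.support
        for n in res.tree.preorder() if n.support is not None
    }
    assert any(s in (clade_a, clade_b) for s in split_supports)


def test_bootstrap_zero_reps_no_supports():
    aln, _ = make_two_clade_alignment(seed=3)
    res = bootstrap_support(aln, n_reps=0)
    assert all(n.support is None for n in res.tree.preorder())


def test_bootstrap_deterministic_per_seed():
    aln, _ = make_two_clade_alignment(seed=5)
    a = bootstrap_support(aln, n_reps=50, seed=11)
    b = bootstrap_support(aln, n_reps=50, seed=11)
    assert write_newick(a.tree) == write_newick(b.tree)
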