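import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import _oracles
from igloci.family_phylo import (
    DistanceMatrix,
    assign_clans,
    assign_families,
    bootstrap_support,
    borderline_pairs,
    identity_matrix,
    nj_tree,
    pairwise_identity,
)
from igloci.genome_io import revcomp
from igloci.synthetic_locus import _make_v_exon_ancestor, _mutate_exon


def rand_seq(seed, n):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), size=n))


def mutate(seq, rate, seed):
    rng = np.random.default_rng(seed)
    out = list(seq)
    sites = rng.choice(len(seq), size=int(round(rate * len(seq))), replace=False)
    for i in sites:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


# ---------------------------------------------------------------------------
# pairwise identity

def test_identity_of_identical_sequences():
    s = rand_seq(0, 300)
    assert pairwise_identity(s, s) == 1.0


def test_identity_single_substitution():
    s = rand_seq(1, 100)
    t = ("G" if s[50] != "G" else "C") + s[51:]
    t = s[:50] + t
    assert pairwise_identity(s, t) == pytest.approx(0.99)


def test_identity_vs_revcomp_is_background():
    s = rand_seq(2, 300)
    assert pairwise_identity(s, revcomp(s)) < 0.7


def test_identity_symmetric_and_validates():
    a, b = rand_seq(3, 200), rand_seq(4, 180)
    assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))
    with pytest.raises(ValueError):
        pairwise_identity("", "ACGT")


# ---------------------------------------------------------------------------
# families

def test_assign_families_trivial_example():
    s1 = rand_seq(5, 300)
    s3 = rand_seq(6, 300)
    fams = assign_families({"s1": s1, "s2": s1, "s3": s3})
    partition = {frozenset(f.members) for f in fams}
    assert partition == {frozenset({"s1", "s2"}), frozenset({"s3"})}


def test_assign_families_single_segment():
    fams = assign_families({"only": rand_seq(7, 300)})
    assert len(fams) == 1 and fams[0].members == ["only"]


def simulate_families(seed, members=(5, 4, 3), within=0.10, between=0.45):
    rng = np.random.default_rng(seed)
    anc0 = _make_v_exon_ancestor(rng)
    ancestors = [anc0] + [_mutate_exon(anc0, between, rng) for _ in members[1:]]
    seqs, truth = {}, {}
    k = 0
    for fam, (anc, m) in enumerate(zip(ancestors, members)):
        for _ in range(m):
            name = f"s{k}"
            seqs[name] = _mutate_exon(anc, within, rng)
            truth[name] = fam
            k += 1
    return seqs, truth


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_assign_families_recovers_planted_partition(seed):
    seqs, truth = simulate_families(seed)
    fams = assign_families(seqs)
    got = {frozenset(f.members) for f in fams}
    want = {frozenset(n for n in truth if truth[n] == f) for f in set(truth.values())}
    assert got == want


def test_family_ordering_by_size_then_position():
    seqs, _ = simulate_families(11, members=(3, 5, 4))
    fams = assign_families(seqs, positions={f"s{i}": i for i in range(12)})
    sizes = [len(f.members) for f in fams]
    assert sizes == sorted(sizes, reverse=True)
    assert [f.family_id for f in fams] == [1, 2, 3]


def test_threshold_monotonicity():
    """Lowering the clustering threshold never increases the family count."""
    seqs, _ = simulate_families(13)
    pre = identity_matrix(seqs)
    counts = [
        len(assign_families(seqs, threshold_same=0.9, threshold_diff=t, precomputed=pre))
        for t in (0.85, 0.70, 0.55, 0.40)
    ]
    assert counts == sorted(counts, reverse=True)


@given(st.integers(0, 10_000))
@settings(max_examples=15, deadline=None)
def test_families_always_partition(seed):
    rng = np.random.default_rng(seed)
    base = rand_seq(seed, 120)
    seqs = {f"s{i}": mutate(base, rng.uniform(0, 0.6), seed + i) for i in range(6)}
    fams = assign_families(seqs)
    members = [m for f in fams for m in f.members]
    assert sorted(members) == sorted(seqs)  # disjoint and covering


def test_borderline_band_reported():
    base = rand_seq(21, 300)
    # ~27% divergence lands in the (0.70, 0.75] identity band often enough;
    # search a few rates for a deterministic in-band pair
    for rate in (0.26, 0.27, 0.28, 0.25):
        other = mutate(base, rate, 99)
        ident = pairwise_identity(base, other)
        if 0.70 < ident <= 0.75:
            pairs = borderline_pairs({"a": base, "b": other})
            assert ("a", "b", pytest.approx(ident)) in [
                (x, y, pytest.approx(v)) for x, y, v in pairs
            ]
            return
    pytest.fail("could not construct a borderline pair")


def test_threshold_validation():
    seqs = {"a": rand_seq(0, 50), "b": rand_seq(1, 50)}
    with pytest.raises(ValueError):
        assign_families(seqs, threshold_same=0.7, threshold_diff=0.75)
    with pytest.raises(ValueError):
        assign_families(seqs, threshold_diff=1.5)
    with pytest.raises(ValueError):
        assign_families({})


# ---------------------------------------------------------------------------
# neighbor joining

def test_nj_recovers_known_four_taxon_tree():
    # tree ((A:1,B:2):1,(C:3,D:1)): path distances are additive
    d = {
        ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 3,
        ("B", "C"): 6, ("B", "D"): 4, ("C", "D"): 4,
    }
    labels = ["A", "B", "C", "D"]
    m = np.zeros((4, 4))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i != j:
                m[i, j] = d[tuple(sorted((x, y)))]
    tree = nj_tree(DistanceMatrix(labels, m))
    assert tree.bipartitions() == {frozenset({"C", "D"})}
    td = tree.tip_distances()
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i != j:
                k = (td.labels.index(x), td.labels.index(y))
                assert td.d[k] == pytest.approx(m[i, j], abs=1e-9)


def test_nj_three_taxa_closed_form():
    m = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float)
    tree = nj_tree(DistanceMatrix(["a", "b", "c"], m))
    td = tree.tip_distances()
    # for 3 taxa the star resolution reproduces the distances exactly
    ix = {l: i for i, l in enumerate(td.labels)}
    assert td.d[ix["a"], ix["b"]] == pytest.approx(5)
    assert td.d[ix["a"], ix["c"]] == pytest.approx(9)
    assert td.d[ix["b"], ix["c"]] == pytest.approx(8)


def test_nj_degenerate_equal_distances_deterministic():
    m = np.ones((5, 5)) - np.eye(5)
    labels = list("abcde")
    t1 = nj_tree(DistanceMatrix(labels, m.copy())).to_newick()
    t2 = nj_tree(DistanceMatrix(labels, m.copy())).to_newick()
    assert t1 == t2


def test_nj_validation():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0.0]]))


# ---------------------------------------------------------------------------
# bootstrap

def two_clade_alignment(seed=0, n_per_clade=4, ncol=500, between=0.40, within=0.02):
    rng = np.random.default_rng(seed)
    root = rand_seq(seed, ncol)
    anc_a, anc_b = root, mutate(root, between, seed + 1)
    aln = {}
    for i in range(n_per_clade):
        aln[f"A{i}"] = mutate(anc_a, within, seed + 10 + i)
        aln[f"B{i}"] = mutate(anc_b, within, seed + 20 + i)
    return aln


def test_bootstrap_two_clades_high_support():
    aln = two_clade_alignment()
    tree = bootstrap_support(aln, replicates=200, seed=5)
    split = frozenset(k for k in aln if k.startswith("A"))
    names = frozenset(aln)
    from igloci.family_phylo import _canonical_bipartition

    key = _canonical_bipartition(split, names)
    assert key in tree.supports
    assert tree.supports[key] >= 95


def test_bootstrap_single_replicate_support_binary():
    aln = two_clade_alignment(seed=3)
    tree = bootstrap_support(aln, replicates=1, seed=1)
    assert set(tree.supports.values()) <= {0.0, 100.0}


def test_bootstrap_identical_sequences_star():
    aln = {f"s{i}": "ACGT" * 50 for i in range(5)}
    tree = bootstrap_support(aln, replicates=5, seed=0)
    # no resolvable internal structure: every branch length is zero
    td = tree.tip_distances()
    assert np.allclose(td.d, 0)


def test_bootstrap_invariant_to_leaf_order():
    aln = two_clade_alignment(seed=9)
    t1 = bootstrap_support(aln, replicates=50, seed=4)
    reordered = dict(reversed(list(aln.items())))
    t2 = bootstrap_support(reordered, replicates=50, seed=4)
    assert t1.supports == t2.supports


def test_bootstrap_validation():
    aln = two_clade_alignment()
    with pytest.raises(ValueError):
        bootstrap_support(aln, replicates=0)
    with pytest.raises(ValueError):
        bootstrap_support({"a": "ACGT", "b": "ACGT", "c": "ACGT"}, replicates=10)
    with pytest.raises(ValueError):
        bootstrap_support({"a": "ACGT", "b": "ACG", "c": "ACGT", "d": "ACGT"})


# ---------------------------------------------------------------------------
# clans

def test_assign_clans_by_nearest_reference_clade():
    rng = np.random.default_rng(42)
    ref_ii = _make_v_exon_ancestor(rng)
    ref_iii = _mutate_exon(ref_ii, 0.45, rng)
    seg = _mutate_exon(ref_ii, 0.10, rng)
    refs = {
        "hs_II_a": (ref_ii, "II"),
        "hs_II_b": (_mutate_exon(ref_ii, 0.08, rng), "II"),
        "hs_III_a": (ref_iii, "III"),
        "hs_III_b": (_mutate_exon(ref_iii, 0.08, rng), "III"),
    }
    out = assign_clans({"gp_V1": seg}, refs)
    assert out == {"gp_V1": "II"}


def test_assign_clans_tie_is_unassigned():
    # the segment's nearest reference clade is a sister pair holding one
    # reference of each clan: the vote ties -> unassigned
    anc = rand_seq(1, 300)
    refs = {
        "rA": (mutate(anc, 0.02, 10), "I"),
        "rB": (mutate(anc, 0.02, 11), "II"),
        "rC": (rand_seq(2, 300), "I"),  # distant outgroup
    }
    out = assign_clans({"seg": mutate(anc, 0.15, 12)}, refs)
    assert out == {"seg": "unassigned"}


def test_assign_clans_requires_two_clans():
    with pytest.raises(ValueError):
        assign_clans({"s": rand_seq(0, 100)}, {"r": (rand_seq(1, 100), "II")})
    with pytest.raises(ValueError):
        assign_clans({"s": rand_seq(0, 100)}, {})
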