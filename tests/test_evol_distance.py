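"""Distances and trees: closed-form oracles, brute-force quartet checks,
and independent cross-checks against dendropy and R ape."""

import itertools
import shutil
import subprocess

import numpy as np
import pytest

from chiromito.evol_distance import (
    Alignment,
    DistanceError,
    DistanceMatrix,
    bootstrap_support,
    distance_matrix,
    dual_triangle_table,
    jc69_closed_form,
    k2p_closed_form,
    ml_distance,
    nj_tree,
    p_distance,
)


def _pair_with_p(p, n=6000):
    k = int(round(p * n))
    return "A" * n, "C" * k + "A" * (n - k)


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

def test_p_distance_hand_counts():
    assert p_distance("ACGTACGTAC", "ACGTACGTAC") == 0.0
    assert p_distance("ACGTACGTAC", "TCGTACGTAC") == pytest.approx(0.1)
    # gap in either row excludes the site (pairwise deletion)
    assert p_distance("AC-GT", "ACAGA") == pytest.approx(0.25)


def test_p_distance_no_comparable_sites():
    with pytest.raises(DistanceError):
        p_distance("---", "AAA")
    with pytest.raises(DistanceError):
        p_distance("ACG", "ACGT")  # unequal lengths


# ---------------------------------------------------------------------------
# ML distances vs analytic oracles
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p", [0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 0.6, 0.7])
def test_jc69_matches_closed_form(p):
    a, b = _pair_with_p(p)
    obs_p = p_distance(a, b)
    assert ml_distance(a, b, "JC69") == pytest.approx(
        jc69_closed_form(obs_p), abs=1e-9
    )


def test_jc69_saturation_reported_as_infinite():
    a, b = _pair_with_p(0.80)
    assert ml_distance(a, b, "JC69") == float("inf")


def test_k2p_transitions_only_closed_form():
    # P = 0.1, Q = 0: -1/2 ln(1-2P) - 1/4 ln(1) = 0.11157
    n, k = 10000, 1000
    d = ml_distance("A" * n, "G" * k + "A" * (n - k), "K2P")
    assert k2p_closed_form(0.1, 0.0) == pytest.approx(0.111572, abs=1e-5)
    assert d == pytest.approx(k2p_closed_form(0.1, 0.0), abs=1e-4)


def test_k2p_mixed_matches_closed_form():
    n = 10000
    b = "G" * 1000 + "C" * 600 + "A" * (n - 1600)  # P = 0.1, Q = 0.06
    assert ml_distance("A" * n, b, "K2P") == pytest.approx(
        k2p_closed_form(0.1, 0.06), abs=1e-4
    )


def test_k2p_reduces_to_jc_on_jc_like_data():
    rng = np.random.default_rng(1)
    bases = np.array(list("ACGT"))
    s1 = rng.choice(bases, 3000)
    s2 = s1.copy()
    idx = rng.choice(3000, 300, replace=False)
    s2[idx] = rng.choice(bases, 300)
    a, b = "".join(s1), "".join(s2)
    assert ml_distance(a, b, "K2P") == pytest.approx(
        jc69_closed_form(p_distance(a, b)), rel=1e-3
    )


@pytest.mark.parametrize("model", ["JC69", "K2P", "TN93"])
def test_ml_at_least_p(model):
    """Multiple-hit correction is monotone: d_ML >= p on every pair."""
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    for _ in range(4):
        s1 = rng.choice(bases, 800, p=[0.3, 0.27, 0.13, 0.3])
        s2 = s1.copy()
        n_mut = int(rng.integers(20, 300))
        idx = rng.choice(800, n_mut, replace=False)
        s2[idx] = rng.choice(bases, n_mut)
        a, b = "".join(s1), "".join(s2)
        p = p_distance(a, b)
        assert ml_distance(a, b, model) >= p - 1e-12


def test_zero_distance_under_every_model():
    a = "ACGT" * 100
    for model in ("JC69", "K2P", "TN93"):
        assert ml_distance(a, a, model) == 0.0


def test_tn93_agrees_with_r_ape():
    """Cross-check the TN93 fit against ape::dist.dna's closed form;
    ML and moment estimators agree closely on well-behaved data."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript unavailable; TN93 cross-check cannot run")
    rng = np.random.default_rng(42)
    base = "".join(rng.choice(list("ACGT"), p=[0.31, 0.26, 0.13, 0.30], size=1500))
    s = list(base)
    trs = {"A": "G", "G": "A", "C": "T", "T": "C"}
    for i in rng.choice(1500, 180, replace=False):
        s[i] = trs[s[i]] if rng.random() < 0.7 else rng.choice(
            [b for b in "ACGT" if b != s[i]]
        )
    other = "".join(s)
    rcode = (
        'library(ape); '
        f'm <- rbind(strsplit("{base}", "")[[1]], strsplit("{other}", "")[[1]]); '
        'rownames(m) <- c("a","b"); '
        'cat(sprintf("%.8f", as.numeric(dist.dna(as.DNAbin(m), model="TN93", '
        'pairwise.deletion=TRUE))))'
    )
    out = subprocess.run(
        ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=120
    )
    assert out.returncode == 0, out.stderr
    assert ml_distance(base, other, "TN93") == pytest.approx(
        float(out.stdout), rel=0.01
    )


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def test_distance_matrix_symmetric_zero_diagonal():
    aln = Alignment(["a", "b", "c"], ["ACGTACGT", "ACGTACGA", "ACGAACTA"])
    dm = distance_matrix(aln, "p")
    assert np.allclose(dm.values, dm.values.T)
    assert np.allclose(np.diag(dm.values), 0)
    assert dm.method == "p"


def test_distance_matrix_validation():
    with pytest.raises(DistanceError):
        DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]), "p")  # asymmetric
    with pytest.raises(DistanceError):
        DistanceMatrix(["a", "b"], np.array([[1.0, 0], [0, 0]]), "p")  # diagonal


def test_dual_triangle_two_gene_layout():
    taxa = ["t1", "t2", "t3"]
    m1 = DistanceMatrix(taxa, np.array([[0, 0.05, 0.128], [0.05, 0, 0.132], [0.128, 0.132, 0]]), "ML(TN93) ND1")
    m2 = DistanceMatrix(taxa, np.array([[0, 0.037, 0.094], [0.037, 0, 0.096], [0.094, 0.096, 0]]), "p ND1")
    table = dual_triangle_table(m1, m2)
    lines = table.strip().splitlines()
    assert lines[0].startswith("# upper triangle: ML(TN93) ND1")
    row_t2 = lines[3].split("\t")
    assert row_t2[1] == "3.7"  # lower triangle, percent scale
    assert row_t2[3] == "13.2"  # upper triangle


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _additive_matrix(rng=None):
    """Distances on the 5-taxon tree ((A,B),C,(D,E)) with known branch
    lengths; returns the matrix and the generating splits."""
    taxa = list("ABCDE")
    pend = {"A": 1.0, "B": 2.0, "C": 4.0, "D": 6.0, "E": 7.0}
    group = {"A": "AB", "B": "AB", "C": "C", "D": "DE", "E": "DE"}
    center = {"A": 4.0, "B": 5.0, "C": 4.0, "D": 11.0, "E": 12.0}  # + internal
    D = np.zeros((5, 5))
    for i, x in enumerate(taxa):
        for j, y in enumerate(taxa):
            if i < j:
                d = pend[x] + pend[y] if group[x] == group[y] else center[x] + center[y]
                D[i, j] = D[j, i] = d
    return taxa, D, {frozenset("AB"), frozenset("DE")}


def _quartet_oracle(taxa, D):
    """Brute force: resolve every quartet by the four-point condition."""
    idx = {t: i for i, t in enumerate(taxa)}
    resolved = set()
    for q in itertools.combinations(taxa, 4):
        best = min(
            (
                (D[idx[a], idx[b]] + D[idx[c], idx[d]], frozenset([frozenset([a, b]), frozenset([c, d])]))
                for a, b, c, d in [
                    (q[0], q[1], q[2], q[3]),
                    (q[0], q[2], q[1], q[3]),
                    (q[0], q[3], q[1], q[2]),
                ]
            ),
            key=lambda x: x[0],
        )
        resolved.add(best[1])
    return resolved


def _tree_quartets(tree):
    taxa = sorted(tree.leaves())
    splits = tree.splits()
    out = set()
    for q in itertools.combinations(taxa, 4):
        for s in splits:
            inside = [t for t in q if t in s]
            outside = [t for t in q if t not in s]
            if len(inside) == 2:
                out.add(frozenset([frozenset(inside), frozenset(outside)]))
    return out


def test_nj_recovers_additive_topology_with_exact_lengths():
    taxa, D, want_splits = _additive_matrix()
    tree = nj_tree(DistanceMatrix(taxa, D, "p"))
    splits = {min(s, frozenset(taxa) - s, key=lambda x: (len(x), sorted(x))) for s in tree.splits()}
    assert splits == want_splits
    # brute-force four-point oracle agrees with every resolved quartet
    assert _tree_quartets(tree) == _quartet_oracle(taxa, D)


def test_nj_on_random_additive_matrices_matches_quartet_oracle():
    rng = np.random.default_rng(5)
    import random as _random

    for _ in range(20):
        # random binary tree over 5 taxa via random agglomeration; each
        # group tracks the path length from every member to its root
        taxa = list("ABCDE")
        D = np.zeros((5, 5))
        r = _random.Random(int(rng.integers(1 << 30)))
        groups = [(frozenset([t]), {t: r.uniform(0.1, 1.0)}) for t in taxa]
        while len(groups) > 1:
            i, j = r.sample(range(len(groups)), 2)
            gi, gj = groups[max(i, j)], groups[min(i, j)]
            groups = [g for k, g in enumerate(groups) if k not in (i, j)]
            li, lj = r.uniform(0.1, 1.0), r.uniform(0.1, 1.0)
            for a in gi[0]:
                for b in gj[0]:
                    ia, ib = taxa.index(a), taxa.index(b)
                    D[ia, ib] = D[ib, ia] = gi[1][a] + gj[1][b]
            merged = {a: d + li for a, d in gi[1].items()}
            merged.update({b: d + lj for b, d in gj[1].items()})
            groups.append((gi[0] | gj[0], merged))
        tree = nj_tree(DistanceMatrix(taxa, D, "p"))
        assert _tree_quartets(tree) == _quartet_oracle(taxa, D)


def test_nj_three_taxa_three_point_formulas():
    D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    tree = nj_tree(DistanceMatrix(["a", "b", "c"], D, "p"))
    lengths = {child.name: l for child, l in tree.children}
    assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
    assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
    assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))


def test_nj_ultrametric_four_taxa():
    taxa = ["w", "x", "y", "z"]
    D = np.array(
        [
            [0.0, 0.2, 0.8, 0.8],
            [0.2, 0.0, 0.8, 0.8],
            [0.8, 0.8, 0.0, 0.4],
            [0.8, 0.8, 0.4, 0.0],
        ]
    )
    tree = nj_tree(DistanceMatrix(taxa, D, "p"))
    splits = tree.splits()
    assert frozenset(["w", "x"]) in splits or frozenset(["y", "z"]) in splits


def test_nj_branch_lengths_never_negative():
    rng = np.random.default_rng(11)
    for _ in range(10):
        n = 6
        pts = rng.uniform(0, 1, size=(n, 4))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)  # metric, non-additive
        tree = nj_tree(DistanceMatrix([f"t{i}" for i in range(n)], D, "p"))

        def walk(node):
            for child, length in node.children:
                assert length >= 0.0
                walk(child)

        walk(tree)


def test_nj_matches_dendropy_topology():
    """Independent implementation check: same additive matrix, same
    topology (RF distance 0) as dendropy's NJ."""
    dendropy = pytest.importorskip("dendropy")
    import io as _io
    from dendropy.calculate import treecompare

    taxa, D, _ = _additive_matrix()
    csv = "," + ",".join(taxa) + "\n" + "\n".join(
        t + "," + ",".join(str(D[i, j]) for j in range(5)) for i, t in enumerate(taxa)
    ) + "\n"
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=_io.StringIO(csv), delimiter=",")
    dtree = pdm.nj_tree()
    mine = dendropy.Tree.get(
        data=nj_tree(DistanceMatrix(taxa, D, "p")).newick(),
        schema="newick",
        taxon_namespace=dtree.taxon_namespace,
    )
    dtree.encode_bipartitions()
    mine.encode_bipartitions()
    assert treecompare.symmetric_difference(dtree, mine) == 0


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _two_clade_alignment(seed=0, n_sites=400, inner=5, between=120):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def mutate(s, n):
        s = list(s)
        for i in rng.choice(len(s), n, replace=False):
            s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
        return "".join(s)

    base = "".join(rng.choice(bases, n_sites))
    other = mutate(base, between)
    return Alignment(
        ["a1", "a2", "b1", "b2"],
        [mutate(base, inner), mutate(base, inner), mutate(other, inner), mutate(other, inner)],
    )


def test_bootstrap_strong_signal():
    aln = _two_clade_alignment(seed=0)
    tree = bootstrap_support(aln, method="p", n_reps=100, seed=3)
    supports = []

    def walk(node):
        for child, _ in node.children:
            if child.support is not None:
                supports.append(child.support)
            walk(child)

    walk(tree)
    assert supports and min(supports) >= 95.0


def test_bootstrap_single_replicate_support_is_binary():
    aln = _two_clade_alignment(seed=2)
    tree = bootstrap_support(aln, method="p", n_reps=1, seed=0)

    def walk(node):
        for child, _ in node.children:
            if child.support is not None:
                assert child.support in (0.0, 100.0)
            walk(child)

    walk(tree)


def test_bootstrap_deterministic_for_fixed_seed():
    aln = _two_clade_alignment(seed=4)
    t1 = bootstrap_support(aln, method="p", n_reps=50, seed=9)
    t2 = bootstrap_support(aln, method="p", n_reps=50, seed=9)
    assert t1.newick(with_support=True) == t2.newick(with_support=True)
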