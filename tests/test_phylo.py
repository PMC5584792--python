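"""Trimming, distances, neighbor joining and bootstrap support."""

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

import riboregulon as rb
from riboregulon._jtt import AA_ORDER, JTT_FREQS, jtt_rate_matrix
from riboregulon.phylo import (DISTANCE_CAP, _distances_from_codes,
                               attach_supports, bipartitions, write_newick)


# ---------------------------------------------------------------------------
# trimming


def test_trim_keeps_boundary_column():
    """A column with exactly 20% gaps survives; 30% is removed."""
    rows_20 = ["A"] * 8 + ["-"] * 2
    rows_30 = ["C"] * 7 + ["-"] * 3
    rows_00 = ["G"] * 10
    msa = rb.MSA([f"t{i}" for i in range(10)],
                 ["".join(t) for t in zip(rows_20, rows_30, rows_00)])
    out = rb.trim_alignment(msa, max_gap=0.20)
    assert out.n_cols == 2
    assert [r[0] for r in out.rows[:8]] == ["A"] * 8   # 20% column kept
    assert all(r[1] == "G" for r in out.rows)          # 30% column removed


@pytest.mark.parametrize("nrows", [5, 10, 20])
def test_trim_boundary_inclusive_at_various_depths(nrows):
    ngap = nrows // 5          # exactly 20%
    col = ["A"] * (nrows - ngap) + ["-"] * ngap
    msa = rb.MSA([f"t{i}" for i in range(nrows)], [c for c in col])
    assert rb.trim_alignment(msa, 0.20).n_cols == 1


def test_trim_gap_free_is_identity():
    msa = rb.MSA(["a", "b"], ["ACDEF", "ACDEG"])
    assert rb.trim_alignment(msa).rows == msa.rows


def test_trim_everything_removed_raises():
    msa = rb.MSA(["a", "b"], ["-A", "A-"])
    with pytest.raises(ValueError):
        rb.trim_alignment(msa, 0.2)


# ---------------------------------------------------------------------------
# concatenation


def test_concat_widths_and_offsets():
    f1 = rb.MSA(["a", "b"], ["A" * 100, "C" * 100])
    f2 = rb.MSA(["b", "a"], ["D" * 50, "E" * 50])
    cat, offs = rb.concat_alignments([f1, f2], ["a", "b"])
    assert cat.n_cols == 150
    assert offs == [(0, 100), (100, 150)]
    assert cat.rows[0] == "A" * 100 + "E" * 50   # rows follow the taxon list


def test_concat_single_family_is_identity():
    f1 = rb.MSA(["a", "b"], ["ACD", "ACE"])
    cat, offs = rb.concat_alignments([f1], ["a", "b"])
    assert cat.rows == f1.rows and offs == [(0, 3)]


def test_concat_missing_taxon_is_reported():
    f1 = rb.MSA(["a", "b"], ["ACD", "ACE"])
    with pytest.raises(ValueError, match="c"):
        rb.concat_alignments([f1], ["a", "b", "c"])


def test_concat_offsets_partition_total(species_tree_12):
    tree, taxonomy = species_tree_12
    cfg = rb.SimConfig(seed=15, n_marker_families=20, family_length=37)
    fams, _ = rb.evolve_families(tree, cfg)
    msas = [rb.MSA([l for l, _ in r], [s for _, s in r]) for r in fams.values()]
    cat, offs = rb.concat_alignments(msas, sorted(taxonomy))
    assert offs[0][0] == 0 and offs[-1][1] == cat.n_cols
    assert all(a[1] == b[0] for a, b in zip(offs, offs[1:]))


# ---------------------------------------------------------------------------
# distances


def test_identical_rows_zero_distance_all_methods():
    msa = rb.MSA(["a", "b"], ["ACDEFGHIKL" * 5] * 2)
    for method in ("p", "poisson", "jtt_ml"):
        assert rb.protein_distance(msa, method).matrix[0, 1] == pytest.approx(0.0)


def test_poisson_closed_form():
    row_a = "A" * 100
    row_b = "A" * 90 + "R" * 10
    msa = rb.MSA(["a", "b"], [row_a, row_b])
    d = rb.protein_distance(msa, "poisson").matrix[0, 1]
    assert d == pytest.approx(-np.log(0.9), abs=1e-12)


def test_pairwise_deletion_ignores_gapped_columns():
    msa = rb.MSA(["a", "b"], ["AC-EF", "ACD-F"])
    d = rb.protein_distance(msa, "p").matrix[0, 1]
    assert d == 0.0   # only columns 0,1,4 compared


def test_poisson_saturation_capped_with_warning():
    msa = rb.MSA(["a", "b"], ["A" * 50, "R" * 50])
    with pytest.warns(UserWarning, match="saturat"):
        d = rb.protein_distance(msa, "poisson").matrix[0, 1]
    assert d == DISTANCE_CAP


def _simulate_jtt_pair(t, n_sites, rng):
    """Independent pair simulation straight from the published rate matrix."""
    q = jtt_rate_matrix()
    p = expm(q * t)
    anc = rng.choice(20, size=n_sites, p=JTT_FREQS)
    der = np.array([rng.choice(20, p=p[a]) for a in anc])
    return ("".join(AA_ORDER[i] for i in anc), "".join(AA_ORDER[i] for i in der))


def test_jtt_ml_recovers_simulated_distance():
    rng = np.random.default_rng(8)
    a, b = _simulate_jtt_pair(0.3, 5000, rng)
    msa = rb.MSA(["anc", "der"], [a, b])
    d = rb.protein_distance(msa, "jtt_ml").matrix[0, 1]
    assert abs(d - 0.3) < 0.03


def test_jtt_ml_larger_than_p_distance():
    rng = np.random.default_rng(9)
    a, b = _simulate_jtt_pair(0.5, 2000, rng)
    msa = rb.MSA(["x", "y"], [a, b])
    p = rb.protein_distance(msa, "p").matrix[0, 1]
    ml = rb.protein_distance(msa, "jtt_ml").matrix[0, 1]
    assert ml > p   # multiple hits corrected


# ---------------------------------------------------------------------------
# neighbor joining


def random_additive_case(n_taxa, rng):
    """Random binary tree with branch lengths; returns (tree, path-distance DM)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    newick_parts = {l: l for l in labels}
    active = list(labels)
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        del active[j], active[i]
        la, lb = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        merged = f"({newick_parts.pop(a)}:{la:.6f},{newick_parts.pop(b)}:{lb:.6f})"
        key = min(a, b)
        newick_parts[key] = merged
        active.append(key)
    a, b = active
    l = rng.uniform(0.2, 1.0)
    nwk = f"({newick_parts[a]}:{l / 2:.6f},{newick_parts[b]}:{l / 2:.6f});"
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace}
    m = np.array([[pdm.patristic_distance(tx[x], tx[y]) if x != y else 0.0
                   for y in labels] for x in labels])
    return tree, rb.DistanceMatrix(labels, m)


def test_two_taxa_single_edge_split_evenly():
    dm = rb.DistanceMatrix(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]]))
    tree = rb.nj_build(dm)
    lengths = sorted(l.edge.length for l in tree.leaf_node_iter())
    assert lengths == [1.5, 1.5]


def test_four_taxon_additive_matrix_recovered_exactly():
    gen = dendropy.Tree.get(data="((A:1,B:2):1,(C:3,D:4):0);", schema="newick")
    labels = ["A", "B", "C", "D"]
    pdm = gen.phylogenetic_distance_matrix()
    tx = {t.label: t for t in gen.taxon_namespace}
    m = np.array([[pdm.patristic_distance(tx[x], tx[y]) if x != y else 0.0
                   for y in labels] for x in labels])
    tree = rb.nj_build(rb.DistanceMatrix(labels, m))
    assert bipartitions(tree) == bipartitions(gen)
    out = tree.phylogenetic_distance_matrix()
    tx2 = {t.label: t for t in tree.taxon_namespace}
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i < j:
                assert out.patristic_distance(tx2[x], tx2[y]) == \
                    pytest.approx(m[i, j], abs=1e-9)


def test_nj_exact_on_random_additive_matrices():
    rng = np.random.default_rng(12)
    for _ in range(25):
        n = int(rng.integers(4, 9))
        gen, dm = random_additive_case(n, rng)
        est = rb.nj_build(dm)
        assert bipartitions(est) == bipartitions(gen)
        pdm = est.phylogenetic_distance_matrix()
        tx = {t.label: t for t in est.taxon_namespace}
        for i, x in enumerate(dm.labels):
            for j, y in enumerate(dm.labels):
                if i < j:
                    assert pdm.patristic_distance(tx[x], tx[y]) == \
                        pytest.approx(dm.matrix[i, j], abs=1e-9)


def test_nj_topology_invariant_under_taxon_permutation():
    rng = np.random.default_rng(13)
    _, dm = random_additive_case(6, rng)
    t1 = rb.nj_build(dm)
    perm = rng.permutation(len(dm.labels))
    labels2 = [dm.labels[i] for i in perm]
    m2 = dm.matrix[np.ix_(perm, perm)]
    t2 = rb.nj_build(rb.DistanceMatrix(labels2, m2))
    assert bipartitions(t1) == bipartitions(t2)


def test_nj_rejects_asymmetric_matrix():
    with pytest.raises(ValueError):
        rb.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_negative_branch_clamped_with_warning():
    # triangle-inequality violation forces v_c = (1 + 1 - 10)/2 < 0
    m = np.array([[0.0, 10.0, 1.0],
                  [10.0, 0.0, 1.0],
                  [1.0, 1.0, 0.0]])
    with pytest.warns(UserWarning, match="negative branch"):
        tree = rb.nj_build(rb.DistanceMatrix(list("abc"), m))
    assert all(l.edge.length >= 0 for l in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# bootstrap


def test_fixed_clade_gets_full_support():
    """A bipartition present in every column resample has support 1.0."""
    # every single column has pattern X X Y Y, so any resample keeps the split
    msa = rb.MSA(["a", "b", "c", "d"],
                 ["ARND", "ARND", "GQEG", "GQEG"])
    tree = rb.bootstrap_support(msa, n_reps=50, method="p", seed=1)
    sup = [n.support for n in tree.preorder_internal_node_iter()
           if getattr(n, "support", None) is not None]
    assert sup and all(s == pytest.approx(1.0) for s in sup)


def test_two_replicate_supports_match_manual_rerun():
    """Hand-running the two resampled matrices reproduces the supports."""
    msa = rb.MSA(["a", "b", "c", "d"],
                 ["ARNDCQEG", "ARNDCQEA", "GGNDCQRR", "GGNDCQRG"])
    seed, method = 5, "p"
    tree = rb.bootstrap_support(msa, n_reps=2, method=method, seed=seed)
    # manual replay with the same generator
    rng = np.random.default_rng(seed)
    base = rb.nj_build(rb.protein_distance(msa, method))
    want = {bp: 0 for bp in bipartitions(base)}
    codes = msa.codes()
    for _ in range(2):
        cols = rng.integers(0, msa.n_cols, size=msa.n_cols)
        d = _distances_from_codes(codes[:, cols], msa.labels, method)
        rep = rb.nj_build(rb.DistanceMatrix(list(msa.labels), d))
        for bp in bipartitions(rep):
            if bp in want:
                want[bp] += 1
    got = {}
    leaves = sorted(msa.labels)
    for n in tree.preorder_internal_node_iter():
        if getattr(n, "support", None) is not None:
            side = {l.taxon.label for l in n.leaf_iter()}
            if leaves[0] in side:
                side = set(leaves) - side
            got[frozenset(side)] = n.support
    assert got == {bp: c / 2 for bp, c in want.items()}


def test_bootstrap_supports_invariant_to_taxon_order():
    msa = rb.MSA(["a", "b", "c", "d", "e"],
                 ["ARNDCQEGHI", "ARNDCQEGHA", "GGNDCQRRHI", "GGNDCQRRHA",
                  "GGNDCQRGHA"])
    t1 = rb.bootstrap_support(msa, n_reps=20, method="p", seed=3)
    order = [3, 1, 4, 0, 2]
    msa2 = rb.MSA([msa.labels[i] for i in order], [msa.rows[i] for i in order])
    t2 = rb.bootstrap_support(msa2, n_reps=20, method="p", seed=3)

    def supports(tree):
        leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
        out = {}
        for n in tree.preorder_internal_node_iter():
            if getattr(n, "support", None) is not None:
                side = {l.taxon.label for l in n.leaf_iter()}
                if leaves[0] in side:
                    side = set(leaves) - side
                out[frozenset(side)] = n.support
        return out

    assert supports(t1) == supports(t2)


def test_newick_writer_honors_display_threshold(tmp_path):
    msa = rb.MSA(["a", "b", "c", "d"], ["AAAA", "AAAC", "RRRR", "RRRC"])
    tree = rb.bootstrap_support(msa, n_reps=10, method="p", seed=2)
    # force one support below threshold
    for n in tree.preorder_internal_node_iter():
        if getattr(n, "support", None) is not None:
            n.support = 0.4
            break
    path = tmp_path / "t.nwk"
    write_newick(tree, str(path), support_threshold=0.5)
    text = path.read_text()
    assert "0.400" not in text
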