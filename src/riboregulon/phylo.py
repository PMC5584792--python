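"""Alignment trimming, protein distances, neighbor-joining and bootstrap.

The tree-building recipe mirrors standard distance phylogenetics practice:
alignment columns with more than a gap-fraction cutoff (default 20%) are
trimmed, per-family alignments of universally present markers are
concatenated into a super-gene alignment, pairwise evolutionary distances
are computed (p-distance, Poisson correction, or pairwise maximum likelihood
under the JTT rate matrix, in substitutions per site), and trees are built
by Saitou-Nei neighbor joining with column-resampling bootstrap support on
internal edges.

Gap handling is pairwise deletion: each pair of rows ignores columns where
either has a gap.  NJ ties are broken by lexicographic taxon-pair order so
results are deterministic; negative branch lengths are clamped to zero with
a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from Bio import AlignIO
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar

from ._jtt import AA_ORDER, JTT_FREQS, jtt_rate_matrix

GAP_CHARS = "-."
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

POISSON_SATURATION = 0.99
DISTANCE_CAP = 10.0


@dataclass
class MSA:
    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def gap_fraction(self) -> np.ndarray:
        arr = self.to_array()
        return np.isin(arr, list(GAP_CHARS)).mean(axis=0)

    def to_array(self) -> np.ndarray:
        return np.array([list(r.upper()) for r in self.rows])

    def codes(self) -> np.ndarray:
        """Integer residue codes; gaps and unknown letters are -1."""
        arr = self.to_array()
        out = np.full(arr.shape, -1, dtype=np.int8)
        for a, i in _AA_INDEX.items():
            out[arr == a] = i
        return out

    @classmethod
    def from_fasta(cls, path: str) -> "MSA":
        aln = AlignIO.read(path, "fasta")
        return cls([r.id for r in aln], [str(r.seq) for r in aln])

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for l, r in zip(self.labels, self.rows):
                fh.write(f">{l}\n{r}\n")


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (m < 0).any() or not np.isfinite(m).all():
            raise ValueError("distances must be finite and nonnegative")
        self.matrix = m

    def to_phylip(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for l, row in zip(self.labels, self.matrix):
                fh.write(l + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# trimming & concatenation


def trim_alignment(msa: MSA, max_gap: float = 0.20) -> MSA:
    """Keep exactly the columns whose gap fraction is <= ``max_gap``.

    The boundary is inclusive: a column with gap fraction equal to the cutoff
    survives ("more than 20% gaps" are removed).
    """
    if not msa.rows:
        raise ValueError("empty alignment")
    frac = msa.gap_fraction()
    keep = np.flatnonzero(frac <= max_gap)
    if keep.size == 0:
        raise ValueError("trimming removed every column")
    return MSA(list(msa.labels), ["".join(r[i] for i in keep) for r in msa.rows])


def concat_alignments(families: Sequence[MSA], taxa: Sequence[str]
                      ) -> tuple[MSA, list[tuple[int, int]]]:
    """Concatenate per-family alignments into a super-gene alignment.

    Every family must contain every taxon (the marker families are chosen to
    be universally present).  Returns the concatenated MSA plus half-open
    column offsets per family, partitioning [0, total).
    """
    taxa = list(taxa)
    for fi, fam in enumerate(families):
        missing = sorted(set(taxa) - set(fam.labels))
        if missing:
            raise ValueError(f"family {fi} missing taxa: {', '.join(missing)}")
    offsets = []
    pos = 0
    parts = {t: [] for t in taxa}
    for fam in families:
        idx = {l: i for i, l in enumerate(fam.labels)}
        for t in taxa:
            parts[t].append(fam.rows[idx[t]])
        offsets.append((pos, pos + fam.n_cols))
        pos += fam.n_cols
    return MSA(taxa, ["".join(parts[t]) for t in taxa]), offsets


# ---------------------------------------------------------------------------
# distances


class _JTTML:
    """Pairwise ML distance machinery under the JTT rate matrix.

    Q is symmetrised as B = D^{1/2} Q D^{-1/2} (D = diag(pi)) and
    eigendecomposed once, so each transition-matrix evaluation is two small
    matrix products.
    """

    def __init__(self) -> None:
        q = jtt_rate_matrix()
        d = np.sqrt(JTT_FREQS)
        b = (q * d[:, None]) / d[None, :]
        self.evals, self.evecs = eigh((b + b.T) / 2)
        self.left = self.evecs / d[:, None]       # D^{-1/2} V
        self.right = (self.evecs * d[:, None]).T  # V^T D^{1/2}

    def transition(self, t: float) -> np.ndarray:
        p = self.left @ (np.exp(self.evals * t)[:, None] * self.right)
        return np.clip(p, 1e-300, None)

    def neg_loglik(self, t: float, counts: np.ndarray) -> float:
        return -(counts * np.log(self.transition(t))).sum()

    def estimate(self, counts: np.ndarray, t_max: float = DISTANCE_CAP) -> float:
        if counts.sum() == 0:
            raise ValueError("no comparable columns")
        off = counts.sum() - np.trace(counts)
        if off == 0:
            return 0.0
        res = minimize_scalar(self.neg_loglik, bounds=(1e-6, t_max),
                              args=(counts,), method="bounded",
                              options={"xatol": 1e-6})
        return float(res.x)


_jtt_ml_singleton: _JTTML | None = None


def _jtt_ml() -> _JTTML:
    global _jtt_ml_singleton
    if _jtt_ml_singleton is None:
        _jtt_ml_singleton = _JTTML()
    return _jtt_ml_singleton


def _distances_from_codes(codes: np.ndarray, labels: Sequence[str],
                          method: str) -> np.ndarray:
    n = codes.shape[0]
    d = np.zeros((n, n))
    ml = _jtt_ml() if method == "jtt_ml" else None
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            valid = (a >= 0) & (b >= 0)
            if not valid.any():
                raise ValueError(
                    f"no comparable columns between {labels[i]} and {labels[j]}")
            if method == "jtt_ml":
                pair = a[valid].astype(np.intp) * 20 + b[valid]
                counts = np.bincount(pair, minlength=400).reshape(20, 20).astype(float)
                counts = (counts + counts.T) / 2  # reversibility: symmetrise
                dij = ml.estimate(counts)
            else:
                p = float((a[valid] != b[valid]).mean())
                if method == "p":
                    dij = p
                elif p >= POISSON_SATURATION:
                    warnings.warn(
                        f"pair ({labels[i]},{labels[j]}) saturated "
                        f"(p={p:.3f}); capping at {DISTANCE_CAP}")
                    dij = DISTANCE_CAP
                else:
                    dij = -np.log(1.0 - p)
            d[i, j] = d[j, i] = dij
    return d


def protein_distance(msa: MSA, method: str = "jtt_ml") -> DistanceMatrix:
    """Pairwise distances in substitutions/site (pairwise gap deletion).

    Methods: ``p`` (mismatch fraction), ``poisson`` (-ln(1 - p)), ``jtt_ml``
    (1-D maximum-likelihood branch time under the JTT model).  Saturated
    pairs (p beyond the correction's reach) are set to the configured cap
    with a warning.
    """
    if len(msa.labels) < 2:
        raise ValueError("need at least 2 taxa")
    if method not in ("p", "poisson", "jtt_ml"):
        raise ValueError(f"unknown method {method!r}")
    d = _distances_from_codes(msa.codes(), msa.labels, method)
    return DistanceMatrix(list(msa.labels), d)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_build(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic lexicographic ties.

    Minimises Q(i,j) = (n-2) d(i,j) - r_i - r_j; among equal-Q pairs the
    lexicographically smallest pair of cluster names (each cluster named by
    its smallest member taxon) is joined.  Negative branch lengths are
    clamped to zero with a warning.  The returned tree is unrooted (the seed
    node is the final 3-way join).
    """
    labels = list(dm.labels)
    n0 = len(labels)
    if n0 < 2:
        raise ValueError("need at least 2 taxa")
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    def leaf(lab: str) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lab)
        return node

    def clamp(x: float, where: str) -> float:
        if x < 0:
            if x < -1e-12:
                warnings.warn(f"negative branch length {x:.3g} at {where}; clamped to 0")
            return 0.0
        return x

    nodes = [leaf(l) for l in labels]
    names = list(labels)          # cluster names (smallest member label)
    d = dm.matrix.copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cands = [(tuple(sorted((names[i], names[j]))), i, j)
                 for i, j in zip(*np.where(np.isclose(q, qmin, rtol=0, atol=1e-12)))
                 if i < j]
        _, i, j = min(cands)
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = clamp(li, f"join({names[i]},{names[j]})")
        nj.edge.length = clamp(lj, f"join({names[i]},{names[j]})")
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([np.hstack([d[np.ix_(keep, keep)], dnew[keep][:, None]]),
                       np.hstack([dnew[keep], [0.0]])])
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [min(names[i], names[j])]

    root = tree.seed_node
    if len(nodes) == 1:
        tree.seed_node = nodes[0]
    elif len(nodes) == 2:
        root.add_child(nodes[0])
        root.add_child(nodes[1])
        nodes[0].edge.length = clamp(d[0, 1] / 2, "final")
        nodes[1].edge.length = clamp(d[0, 1] / 2, "final")
    else:
        for k in range(3):
            a, b = [x for x in range(3) if x != k]
            vk = 0.5 * (d[k, a] + d[k, b] - d[a, b])
            root.add_child(nodes[k])
            nodes[k].edge.length = clamp(vk, "final star join")
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions & bootstrap


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits, each canonicalised as the side NOT containing the
    lexicographically smallest leaf."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    full = set(leaves)
    anchor = leaves[0]
    out = set()
    for node in tree.preorder_internal_node_iter():
        side = {l.taxon.label for l in node.leaf_iter()}
        if len(side) < 2 or len(side) > len(full) - 2:
            continue
        if anchor in side:
            side = full - side
        out.add(frozenset(side))
    return out


def bootstrap_support(msa: MSA, n_reps: int = 100, method: str = "jtt_ml",
                      seed: int = 0) -> dendropy.Tree:
    """NJ tree from the full alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; the support of each
    internal edge of the original tree is the fraction of replicate trees
    containing the same bipartition.  Supports (in [0,1]) are stored on
    ``node.support`` and as internal node labels.
    """
    tree = nj_build(protein_distance(msa, method))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(tree)}
    ncol = msa.n_cols
    codes = msa.codes()
    labels = list(msa.labels)
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        d = _distances_from_codes(codes[:, cols], labels, method)
        rep_bps = bipartitions(nj_build(DistanceMatrix(labels, d)))
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    attach_supports(tree, {bp: c / n_reps for bp, c in counts.items()})
    return tree


def attach_supports(tree: dendropy.Tree, support: dict[frozenset, float]) -> None:
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    full, anchor = set(leaves), leaves[0]
    for node in tree.preorder_internal_node_iter():
        side = {l.taxon.label for l in node.leaf_iter()}
        if len(side) < 2 or len(side) > len(full) - 2:
            node.support = None
            continue
        if anchor in side:
            side = full - side
        node.support = support.get(frozenset(side))
        node.label = None if node.support is None else f"{node.support:.3f}"


def write_newick(tree: dendropy.Tree, path: str, support_threshold: float = 0.5) -> None:
    """Write Newick; internal labels show only supports above the display threshold."""
    t = tree.clone(depth=1)
    for node in t.preorder_internal_node_iter():
        sup = getattr(node, "support", None)
        node.label = f"{sup:.3f}" if sup is not None and sup > support_threshold else None
    t.write(path=path, schema="newick", suppress_rooting=True)
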