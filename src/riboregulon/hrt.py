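"""Horizontal riboswitch/gene transfer detection by tree incongruence.

A transfer is called when a gene-tree leaf nests, with bootstrap support,
inside a clade whose other members all belong to a single foreign taxonomic
group: the smallest well-supported clade containing the leaf and at least
one other leaf is inspected, and if its remaining members are uniformly of a
group different from the leaf's own, the leaf is flagged as a recipient with
that group as donor.  Duplication-followed-by-divergence is called for taxa
contributing two gene copies when one copy sits concordantly with the
taxon's own group while the other clades with a foreign group.

The donor rank is configurable: phylum for cross-phylum transfers, order
for within-phylum cases.  The smart-blast/HGTree corroboration of the
original analysis is replaced by a lightweight nearest-neighbour report of
patristic distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy


@dataclass(frozen=True)
class TaxonAnnotation:
    taxon: str
    species: str = ""
    order: str = ""
    phylum: str = ""
    copy: int = 1

    def group(self, rank: str) -> str:
        if rank == "phylum":
            return self.phylum
        if rank == "order":
            return self.order
        raise ValueError(f"unknown rank {rank!r}")


@dataclass(frozen=True)
class HRTEvent:
    recipient: str                 # gene-tree leaf label
    donor_group: str
    clade: frozenset[str]          # supporting clade leaf set
    support: float
    evidence_kind: str             # foreign_clade | duplication_divergence


class AnnotationError(KeyError):
    """A gene-tree leaf with no taxon annotation."""


def base_taxon(leaf_label: str) -> tuple[str, int]:
    """Split a leaf label into (taxon, copy index); copies are ``taxon|k``."""
    if "|" in leaf_label:
        t, c = leaf_label.rsplit("|", 1)
        return t, int(c)
    return leaf_label, 1


def read_annotations(path: str) -> dict[str, TaxonAnnotation]:
    """TSV columns: taxon, species, order, phylum[, copy]."""
    out = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            f = dict(zip(header, line.rstrip("\n").split("\t")))
            out[f["taxon"]] = TaxonAnnotation(
                f["taxon"], f.get("species", ""), f.get("order", ""),
                f.get("phylum", ""), int(f.get("copy", 1)))
    return out


def _leaf_group(label: str, annotations: Mapping[str, TaxonAnnotation],
                rank: str) -> str:
    taxon, _ = base_taxon(label)
    if taxon not in annotations:
        raise AnnotationError(f"gene-tree leaf {label!r} has no taxon annotation")
    return annotations[taxon].group(rank)


def _supported(node: dendropy.Node, min_support: float) -> bool:
    sup = getattr(node, "support", None)
    if sup is None and node.label:
        try:
            sup = float(node.label)
        except ValueError:
            sup = None
    return sup is not None and sup >= min_support


def _node_support(node: dendropy.Node) -> float:
    sup = getattr(node, "support", None)
    if sup is None and node.label:
        try:
            sup = float(node.label)
        except ValueError:
            sup = None
    return sup if sup is not None else 0.0


def _supported_splits(gene_tree: dendropy.Tree, min_support: float
                      ) -> list[tuple[frozenset[str], float]]:
    """Both sides of every well-supported internal split of the unrooted tree.

    NJ trees are unrooted; a clade "containing" a leaf may appear in the
    rooted representation only as the complement of an internal node, so
    both sides of each split are returned.
    """
    full = frozenset(l.taxon.label for l in gene_tree.leaf_node_iter())
    out = []
    seen = set()
    for node in gene_tree.preorder_internal_node_iter():
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or len(side) > len(full) - 2:
            continue
        if not _supported(node, min_support):
            continue
        key = side if min(side) == min(full) else full - side
        if key in seen:
            continue
        seen.add(key)
        sup = _node_support(node)
        out.append((side, sup))
        out.append((full - side, sup))
    return out


def detect_foreign_clade(gene_tree: dendropy.Tree,
                         annotations: Mapping[str, TaxonAnnotation],
                         rank: str = "phylum",
                         min_support: float = 0.5) -> list[HRTEvent]:
    """Call leaves whose smallest well-supported clade is uniformly foreign.

    For each leaf, the smallest well-supported (>= ``min_support``) split
    side containing it and at least one other leaf is inspected; if the
    other members all belong to a single group different from the leaf's
    own, the leaf is a putative transfer recipient from that group.  One
    event at most per leaf.
    """
    splits = _supported_splits(gene_tree, min_support)
    events = []
    for leaf in gene_tree.leaf_node_iter():
        label = leaf.taxon.label
        own = _leaf_group(label, annotations, rank)
        containing = sorted((s for s, _ in splits if label in s), key=len)
        if not containing:
            continue
        side = containing[0]
        sup = max(sup for s, sup in splits if s == side)
        members = side - {label}
        groups = {_leaf_group(m, annotations, rank) for m in members}
        if len(groups) == 1:
            donor = groups.pop()
            if donor != own:
                events.append(HRTEvent(
                    recipient=label, donor_group=donor, clade=side,
                    support=sup, evidence_kind="foreign_clade"))
    return events


def detect_dup_divergence(gene_tree: dendropy.Tree,
                          annotations: Mapping[str, TaxonAnnotation],
                          rank: str = "order",
                          min_support: float = 0.5) -> list[HRTEvent]:
    """Duplication-followed-by-divergence: one copy concordant, one foreign.

    Only taxa contributing >= 2 copies are considered.  Each copy's smallest
    well-supported clade is classified against the taxon's own group,
    ignoring the taxon's other copies; an event names the foreign-clading
    copy and its clade.
    """
    by_taxon: dict[str, list[dendropy.Node]] = {}
    for leaf in gene_tree.leaf_node_iter():
        t, _ = base_taxon(leaf.taxon.label)
        by_taxon.setdefault(t, []).append(leaf)

    splits = _supported_splits(gene_tree, min_support)
    events = []
    for taxon, leaves in sorted(by_taxon.items()):
        if len(leaves) < 2:
            continue
        own = _leaf_group(leaves[0].taxon.label, annotations, rank)
        own_labels = {l.taxon.label for l in leaves}
        verdicts = []  # (leaf, donor group or None(=mixed), clade, support)
        for leaf in leaves:
            label = leaf.taxon.label
            cands = sorted(((s, sup) for s, sup in splits
                            if label in s and (s - own_labels)),
                           key=lambda kv: len(kv[0]))
            if not cands:
                verdicts.append((leaf, None, frozenset(), 0.0))
                continue
            side, sup = cands[0]
            members = side - own_labels
            groups = {_leaf_group(m, annotations, rank) for m in members}
            donor = groups.pop() if len(groups) == 1 else None
            verdicts.append((leaf, donor, side, sup))
        has_concordant = any(d == own for _, d, _, _ in verdicts)
        if not has_concordant:
            continue
        for leaf, donor, clade, sup in verdicts:
            if donor is not None and donor != own:
                events.append(HRTEvent(
                    recipient=leaf.taxon.label, donor_group=donor,
                    clade=clade, support=sup,
                    evidence_kind="duplication_divergence"))
    return events


# ---------------------------------------------------------------------------
# species-tree concordance


@dataclass
class ConcordanceReport:
    n_shared_leaves: int
    shared_bipartitions: int
    conflicting_gene: int      # in gene tree only
    conflicting_species: int   # in species tree only

    @property
    def symmetric_difference(self) -> int:
        return self.conflicting_gene + self.conflicting_species


def _restricted_bipartitions(tree: dendropy.Tree, keep: set[str]) -> set[frozenset[str]]:
    leaves = sorted(keep)
    anchor = leaves[0]
    out = set()
    for node in tree.preorder_internal_node_iter():
        side = {l.taxon.label for l in node.leaf_iter()} & keep
        if len(side) < 2 or len(side) > len(keep) - 2:
            continue
        if anchor in side:
            side = keep - side
        out.add(frozenset(side))
    return out


def concordance_report(gene_tree: dendropy.Tree,
                       species_tree: dendropy.Tree) -> ConcordanceReport:
    """Shared/conflicting non-trivial bipartitions on the common leaf set."""
    g_leaves = {l.taxon.label for l in gene_tree.leaf_node_iter()}
    s_leaves = {l.taxon.label for l in species_tree.leaf_node_iter()}
    shared = {l for l in g_leaves if base_taxon(l)[0] in
              {base_taxon(x)[0] for x in s_leaves}} & s_leaves
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared leaves; need >= 4")
    bg = _restricted_bipartitions(gene_tree, shared)
    bs = _restricted_bipartitions(species_tree, shared)
    return ConcordanceReport(
        n_shared_leaves=len(shared),
        shared_bipartitions=len(bg & bs),
        conflicting_gene=len(bg - bs),
        conflicting_species=len(bs - bg))


def nearest_neighbors(gene_tree: dendropy.Tree, leaf_label: str,
                      k: int = 5) -> list[tuple[str, float]]:
    """The k leaves closest to a leaf by patristic distance (corroboration hook)."""
    pdm = gene_tree.phylogenetic_distance_matrix()
    target = None
    for t in gene_tree.taxon_namespace:
        if t.label == leaf_label:
            target = t
    if target is None:
        raise AnnotationError(f"leaf {leaf_label!r} not in tree")
    dists = [(t.label, pdm.patristic_distance(target, t))
             for t in gene_tree.taxon_namespace if t is not target]
    return sorted(dists, key=lambda kv: (kv[1], kv[0]))[:k]


def write_events_tsv(events: Sequence[HRTEvent], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("recipient\tdonor_group\tsupport\tevidence_kind\tclade\n")
        for e in events:
            fh.write(f"{e.recipient}\t{e.donor_group}\t{e.support:.3f}\t"
                     f"{e.evidence_kind}\t{','.join(sorted(e.clade))}\n")
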