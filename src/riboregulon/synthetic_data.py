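"""Synthetic genomes, protein families and transporters with planted truth.

The generator emulates the statistical structure the pipeline assumes about
real bacterial data: multi-gene genomes organised into same-strand operons,
riboswitch aptamer motifs planted in 5' leaders at a stated identity to a
generator consensus, marker protein families evolved site-independently
along a known species tree (with optional planted horizontal transfers and
duplications), and transporter proteins with a known number of hydrophobic
transmembrane segments.  Everything is deterministic given the seed, and a
:class:`GroundTruth` record enumerates every plant.

Background DNA is i.i.d. at the configured GC content; genes are annotated
intervals of that background (no codon structure), which suffices because
the aptamer detector is motif-local.  Protein evolution uses a 20-state
Jukes-Cantor-style process (uniform exchangeabilities): along a branch of
length ``b`` the probability that a site differs from its parent is
(19/20)(1 - exp(-(20/19) b r)) with r the configured substitution rate, and
a substituted site is uniform over the other 19 residues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Sequence

import dendropy
import numpy as np

from .genome_context import GeneRecord, Operon
from .phmm_scan import build_phmm, read_seed_alignment, revcomp

AA = "ARNDCQEGHILKMFPSTWYV"
_HYDROPHOBIC = "ILVF"          # Kyte-Doolittle >= 2.8
_POLAR = "DEKRNQSTG"          # Kyte-Doolittle <= -0.4

#: 20-mer embedded in synthetic transporter references; the packaged
#: synthetic domain catalogue matches it with a mismatch budget.
TRANSPORTER_DOMAIN_CORE = "DQSKEWNRGTDESKQNRWTG"


class SizingError(ValueError):
    """Genome too short to host the requested operon layout."""


def packaged_seed_alignment():
    """The packaged synthetic aptamer seed alignment (rows, structure)."""
    path = resources.files("riboregulon.data") / "synthetic_aptamer_seed.sto"
    return read_seed_alignment(str(path))


def default_consensus() -> str:
    """Consensus of the packaged seed alignment; the motif the generator plants."""
    rows, _ = packaged_seed_alignment()
    return build_phmm(rows).consensus


@dataclass
class SimConfig:
    seed: int = 0
    n_genomes: int = 1
    genome_length: int = 10_000
    gc_content: float = 0.5
    motif_identity: float = 0.9
    upstream_offset_range: tuple[int, int] = (20, 150)
    operon_size_range: tuple[int, int] = (2, 5)
    n_marker_families: int = 20
    subst_rate: float = 0.2
    hgt_events: list[tuple] = field(default_factory=list)   # (family, donor clade, recipient)
    dup_events: list[tuple] = field(default_factory=list)   # (family, taxon[, donor clade])
    tm_segment_length: int = 21
    # generator extras
    operons_per_genome: int = 1
    gene_length: int = 600
    intra_operon_gap: int = 30
    family_length: int = 200
    consensus: str | None = None
    dup_rate_factor: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if not 0.0 <= self.motif_identity <= 1.0:
            raise ValueError("motif_identity must lie in [0, 1]")
        for name in ("upstream_offset_range", "operon_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low must be <= high")


@dataclass
class SimGenome:
    genome_id: str
    species: str
    strain: str
    seq: str


@dataclass
class GroundTruth:
    planted_hits: list[tuple[str, int, int, str]] = field(default_factory=list)
    planted_assignments: list[tuple] = field(default_factory=list)  # (hit, kind, target_id)
    hgt_truth: list[tuple] = field(default_factory=list)
    dup_truth: list[tuple] = field(default_factory=list)
    tm_truth: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        gt = cls(**{k: d[k] for k in d})
        gt.planted_hits = [tuple(t) for t in gt.planted_hits]
        gt.planted_assignments = [(tuple(h), k, t) for h, k, t in gt.planted_assignments]
        gt.hgt_truth = [tuple(t) for t in gt.hgt_truth]
        gt.dup_truth = [tuple(t) for t in gt.dup_truth]
        return gt


# ---------------------------------------------------------------------------
# genomes with planted aptamer motifs


def _mutate_motif(consensus: str, identity: float, rng: np.random.Generator) -> str:
    out = []
    for c in consensus:
        if rng.random() <= identity:
            out.append(c)
        else:
            out.append(rng.choice([x for x in "ACGT" if x != c]))
    return "".join(out)


def simulate_genomes(cfg: SimConfig) -> tuple[list[SimGenome], list[GeneRecord],
                                              list[Operon], GroundTruth]:
    """Generate genomes with operons and one planted aptamer per operon.

    Each operon sits on a random strand; the motif is planted on that strand,
    its 3' end within ``upstream_offset_range`` bases of the first gene's
    strand-aware start.  Ground truth enumerates every plant and its target.
    """
    rng = np.random.default_rng(cfg.seed)
    consensus = cfg.consensus or default_consensus()
    mlen = len(consensus)
    off_lo, off_hi = cfg.upstream_offset_range
    sz_lo, sz_hi = cfg.operon_size_range

    # worst-case span of one operon block: leader room for the motif on either
    # strand plus the gene run and padding
    block = 2 * (mlen + off_hi) + sz_hi * (cfg.gene_length + cfg.intra_operon_gap) + 100
    if cfg.operons_per_genome * block > cfg.genome_length:
        raise SizingError(
            f"genome_length={cfg.genome_length} too short for "
            f"{cfg.operons_per_genome} operon(s) needing up to {block} nt each "
            "(motif + max offset + genes + spacing)")

    p = np.array([(1 - cfg.gc_content) / 2, cfg.gc_content / 2,
                  cfg.gc_content / 2, (1 - cfg.gc_content) / 2])
    genomes, genes, operons = [], [], []
    truth = GroundTruth()
    slot = cfg.genome_length // cfg.operons_per_genome

    for gi in range(cfg.n_genomes):
        gid = f"g{gi:03d}"
        arr = rng.choice(list("ACGT"), size=cfg.genome_length, p=p)
        for oi in range(cfg.operons_per_genome):
            strand = "+" if rng.random() < 0.5 else "-"
            n_genes = int(rng.integers(sz_lo, sz_hi + 1))
            offset = int(rng.integers(off_lo, off_hi + 1))
            base = oi * slot + mlen + off_hi + 50
            tags, coords = [], []
            pos = base
            for k in range(n_genes):
                tag = f"{gid}_o{oi}_g{k}"
                coords.append((pos, pos + cfg.gene_length))
                tags.append(tag)
                pos += cfg.gene_length + cfg.intra_operon_gap
            if strand == "-":
                # 5'->3' on minus strand runs right-to-left: first gene is rightmost
                tags = tags[::-1]
            for tag, (s0, e0) in zip(tags[::-1] if strand == "-" else tags,
                                     coords):
                genes.append(GeneRecord(tag, gid, s0, e0, strand,
                                        gene_name=tag, product="simulated protein"))
            oid = f"{gid}_op{oi}"
            operons.append(Operon(oid, gid, tuple(tags), strand))

            motif = _mutate_motif(consensus, cfg.motif_identity, rng)
            if strand == "+":
                first_start = coords[0][0]
                m0 = first_start - offset - mlen
                arr[m0:m0 + mlen] = list(motif)
            else:
                # first gene (5' on minus strand) is the rightmost interval
                first_end = coords[-1][1]
                m0 = first_end + offset
                arr[m0:m0 + mlen] = list(revcomp(motif))
            truth.planted_hits.append((gid, int(m0), int(m0 + mlen), strand))
            truth.planted_assignments.append(
                ((gid, int(m0), int(m0 + mlen), strand), "operon", oid))
        genomes.append(SimGenome(gid, f"species_{gi:03d}", "strain_1", "".join(arr)))
    return genomes, genes, operons, truth


def write_genomes_fasta(genomes: Sequence[SimGenome], path: str) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.genome_id} species={g.species};strain={g.strain}\n")
            for i in range(0, len(g.seq), 70):
                fh.write(g.seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# species trees and evolved marker families


def make_species_tree(n_taxa: int = 12, seed: int = 0,
                      blen_range: tuple[float, float] = (0.1, 0.4)) -> tuple[dendropy.Tree, dict[str, str]]:
    """Random binary species tree of two labelled clades, plus a taxonomy map.

    Taxa ``t00..`` are split evenly into clades labelled ``cladeA`` and
    ``cladeB`` (the clade MRCAs carry these labels); the returned dict maps
    each taxon to its clade, serving as the synthetic phylum annotation.
    """
    if n_taxa < 4:
        raise ValueError("need >= 4 taxa")
    rng = np.random.default_rng(seed)

    def _join(labels: list[str]) -> str:
        nodes = [f"{l}:{rng.uniform(*blen_range):.4f}" for l in labels]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            a, b = nodes[i], nodes[j]
            del nodes[j], nodes[i]
            nodes.append(f"({a},{b}):{rng.uniform(*blen_range):.4f}")
        return nodes[0]

    half = n_taxa // 2
    taxa = [f"t{i:02d}" for i in range(n_taxa)]
    a = _join(taxa[:half])
    b = _join(taxa[half:])
    # label the clade MRCAs; strip the root-adjacent branch length off the label
    a_sub, a_len = a.rsplit(":", 1)
    b_sub, b_len = b.rsplit(":", 1)
    newick = f"({a_sub}cladeA:{a_len},{b_sub}cladeB:{b_len});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    taxonomy = {t: ("cladeA" if i < half else "cladeB") for i, t in enumerate(taxa)}
    return tree, taxonomy


def _evolve_child(parent: np.ndarray, blen: float, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    p_diff = (19 / 20) * (1 - np.exp(-(20 / 19) * blen * rate))
    child = parent.copy()
    hit = rng.random(len(parent)) < p_diff
    if hit.any():
        shift = rng.integers(1, 20, size=int(hit.sum()))
        child[hit] = (child[hit] + shift) % 20
    return child


def _clade_node(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        if node.label == label or (node.taxon and node.taxon.label == label):
            return node
    raise KeyError(f"no clade or taxon labelled {label!r} in species tree")


def evolve_families(species_tree: dendropy.Tree, cfg: SimConfig
                    ) -> tuple[dict[str, list[tuple[str, str]]], GroundTruth]:
    """Evolve aligned protein families along the species tree.

    Families are named ``fam0..``.  For each configured HGT event
    ``(family, donor_clade_label, recipient_taxon)`` the recipient's sequence
    is replaced by a fresh draw from the donor clade's ancestral sequence.
    Duplication events ``(family, taxon[, donor_clade])`` add a second,
    faster-evolving copy labelled ``taxon|2`` (re-drawn from the donor clade
    when a donor is given: duplication followed by divergence).
    """
    leaves = [l.taxon.label for l in species_tree.leaf_node_iter()]
    if len(leaves) < 4:
        raise ValueError("species tree needs >= 4 leaves")
    for ev in cfg.hgt_events:
        if ev[2] not in leaves:
            raise KeyError(f"HGT recipient {ev[2]!r} is not a leaf of the species tree")

    rng = np.random.default_rng(cfg.seed + 1)
    fams: dict[str, list[tuple[str, str]]] = {}
    truth = GroundTruth()
    for fi in range(cfg.n_marker_families):
        fam = f"fam{fi}"
        root_seq = rng.integers(0, 20, size=cfg.family_length)
        node_seq: dict[int, np.ndarray] = {}
        for node in species_tree.preorder_node_iter():
            if node.parent_node is None:
                node_seq[id(node)] = root_seq
            else:
                blen = node.edge.length or 0.1
                node_seq[id(node)] = _evolve_child(
                    node_seq[id(node.parent_node)], blen, cfg.subst_rate, rng)
        seqs = {l.taxon.label: node_seq[id(l)] for l in species_tree.leaf_node_iter()}

        for ev in cfg.hgt_events:
            f, donor, recip = ev[0], ev[1], ev[2]
            if _fam_name(f) != fam:
                continue
            donor_node = _clade_node(species_tree, donor)
            # transfer from an extant lineage inside the donor clade: copy a
            # random donor leaf's parent sequence and evolve it a short way
            donor_leaves = [l for l in donor_node.leaf_iter()
                            if l.taxon.label != recip]
            src_leaf = donor_leaves[int(rng.integers(len(donor_leaves)))]
            src = node_seq[id(src_leaf.parent_node)]
            blen = 0.5 * (src_leaf.edge.length or 0.1)
            seqs[recip] = _evolve_child(src, blen, cfg.subst_rate, rng)
            truth.hgt_truth.append((fam, donor, recip))

        rows = [(t, "".join(AA[i] for i in seqs[t])) for t in sorted(seqs)]

        for ev in cfg.dup_events:
            f, taxon = ev[0], ev[1]
            donor = ev[2] if len(ev) > 2 else None
            if _fam_name(f) != fam:
                continue
            leaf = _clade_node(species_tree, taxon)
            blen = (leaf.edge.length or 0.1) * cfg.dup_rate_factor
            if donor is None:
                src = seqs[taxon]
            else:
                src = node_seq[id(_clade_node(species_tree, donor))]
            copy2 = _evolve_child(src, blen, cfg.subst_rate, rng)
            rows.append((f"{taxon}|2", "".join(AA[i] for i in copy2)))
            truth.dup_truth.append((fam, taxon, donor))
        fams[fam] = rows
    return fams, truth


def _fam_name(f) -> str:
    return f if isinstance(f, str) else f"fam{f}"


# ---------------------------------------------------------------------------
# transporter proteins


def make_transporter_proteins(cfg: SimConfig, n_segments: int,
                              n_proteins: int = 1,
                              with_domain: bool = True,
                              linker_length: int = 25,
                              name_prefix: str = "tp") -> tuple[list[tuple[str, str]], GroundTruth]:
    """Proteins with exactly ``n_segments`` hydrophobic membrane-spanning runs.

    Segments of ``cfg.tm_segment_length`` residues are drawn from strongly
    hydrophobic residues (Kyte-Doolittle window mean > 1.6) and separated by
    polar linkers (window mean < 0).  When ``with_domain`` is set, the
    synthetic transporter domain core is embedded in the N-terminal linker,
    mimicking a conserved family motif.
    """
    if n_segments < 0:
        raise ValueError("n_segments must be >= 0")
    rng = np.random.default_rng(cfg.seed + 2)
    truth = GroundTruth()
    out = []
    for pi in range(n_proteins):
        parts = []
        nterm = "".join(rng.choice(list(_POLAR), size=linker_length + 10))
        if with_domain:
            nterm = nterm[:5] + TRANSPORTER_DOMAIN_CORE + nterm[5:]
        parts.append(nterm)
        for k in range(n_segments):
            parts.append("".join(rng.choice(list(_HYDROPHOBIC),
                                            size=cfg.tm_segment_length)))
            parts.append("".join(rng.choice(list(_POLAR), size=linker_length)))
        name = f"{name_prefix}{pi}"
        out.append((name, "".join(parts)))
        truth.tm_truth[name] = n_segments
    return out, truth


def mutate_protein(seq: str, distance: float, rng: np.random.Generator) -> str:
    """Substitute a ``distance`` fraction of positions with random other residues."""
    s = list(seq)
    n_mut = int(round(distance * len(s)))
    for i in rng.choice(len(s), size=n_mut, replace=False):
        s[i] = rng.choice([a for a in AA if a != s[i]])
    return "".join(s)


def write_protein_fasta(proteins: Sequence[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in proteins:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
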