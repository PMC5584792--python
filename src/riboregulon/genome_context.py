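"""Gene annotations, operon tables and riboswitch-to-target assignment.

A riboswitch aptamer regulates the gene (or operon) immediately downstream of
it on the same strand.  This module reads GFF3 gene annotations and
DOOR-style operon tables, reduces a genome cohort to one representative
strain per species, and maps each aptamer hit to its putative regulatory
target: the nearest same-strand downstream gene within a configurable leader
length, promoted to the whole operon when that gene leads one.

Coordinates are 0-based half-open internally; GFF3 is converted from/to its
1-based inclusive convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import gffutils

from .phmm_scan import RiboswitchHit


class ValidationError(ValueError):
    """A record that violates the file-format or cross-reference contract."""


@dataclass(frozen=True)
class GeneRecord:
    locus_tag: str
    genome_id: str
    start: int          # 0-based half-open
    end: int
    strand: str
    gene_name: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"{self.locus_tag}: start must be < end")
        if self.strand not in "+-":
            raise ValidationError(f"{self.locus_tag}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class Operon:
    operon_id: str
    genome_id: str
    locus_tags: tuple[str, ...]   # 5'->3' on the operon strand
    strand: str

    def __post_init__(self) -> None:
        if len(self.locus_tags) < 1:
            raise ValidationError(f"{self.operon_id}: operon needs >= 1 gene")
        if self.strand not in "+-":
            raise ValidationError(f"{self.operon_id}: bad strand")


@dataclass(frozen=True)
class RegulatoryAssignment:
    hit: RiboswitchHit
    target_kind: str            # gene | operon | none
    target_id: str | None
    distance: int | None        # strand-aware bases from hit end to target start
    note: str = ""


# ---------------------------------------------------------------------------
# strain de-duplication


def dedupe_strains(genomes: Sequence, species_of: dict[str, str] | None = None) -> list:
    """One representative genome per species (lexicographically smallest id).

    ``genomes`` may be any objects with ``genome_id`` and ``species``
    attributes, or bare genome-id strings combined with a ``species_of`` map.
    Re-running on its own output is the identity.
    """
    keyed = []
    for g in genomes:
        if isinstance(g, str):
            if species_of is None or g not in species_of:
                raise ValidationError(f"genome {g!r} has no species label")
            keyed.append((species_of[g], g, g))
        else:
            sp = getattr(g, "species", None)
            if not sp:
                raise ValidationError(f"genome {g.genome_id} has no species label")
            keyed.append((sp, g.genome_id, g))
    best: dict[str, tuple[str, object]] = {}
    for sp, gid, obj in keyed:
        if sp not in best or gid < best[sp][0]:
            best[sp] = (gid, obj)
    return [obj for _, obj in sorted(best.values(), key=lambda t: t[0])]


# ---------------------------------------------------------------------------
# hit -> target assignment


def assign_hit(hit: RiboswitchHit, genes: Sequence[GeneRecord],
               operons: Sequence[Operon], max_upstream: int = 500) -> RegulatoryAssignment:
    """Assign a riboswitch hit to the gene or operon it putatively regulates.

    The candidate is the nearest gene on the hit's strand whose strand-aware
    start lies at or downstream of the hit start, within ``max_upstream``
    bases of the hit end (distance 0 if the hit overlaps the gene start).
    A candidate that leads an operon yields an operon assignment.
    """
    cands = []
    for g in genes:
        if g.genome_id != hit.genome_id or g.strand != hit.strand:
            continue
        if hit.strand == "+":
            if g.start < hit.start:
                continue
            dist = max(0, g.start - hit.end)
        else:
            if g.end > hit.end:
                continue
            dist = max(0, hit.start - g.end)
        if dist <= max_upstream:
            cands.append((dist, g.start, g))
    if not cands:
        return RegulatoryAssignment(hit, "none", None, None, "no same-strand downstream gene")
    dist, _, gene = min(cands, key=lambda t: (t[0], t[1]))
    for op in operons:
        if op.genome_id == hit.genome_id and op.locus_tags[0] == gene.locus_tag:
            return RegulatoryAssignment(hit, "operon", op.operon_id, dist)
    return RegulatoryAssignment(hit, "gene", gene.locus_tag, dist)


# ---------------------------------------------------------------------------
# readers / writers


def read_gff3(path: str, genome_lengths: dict[str, int] | None = None,
              feature_types: tuple[str, ...] = ("CDS",)) -> list[GeneRecord]:
    """Parse CDS features from GFF3 into :class:`GeneRecord` (0-based half-open)."""
    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes = []
    for ft in feature_types:
        for f in db.features_of_type(ft, order_by=("seqid", "start")):
            locus = (f.attributes.get("locus_tag") or f.attributes.get("ID") or [f.id])[0]
            start0, end0 = f.start - 1, f.end
            if genome_lengths is not None:
                glen = genome_lengths.get(f.seqid)
                if glen is not None and not (0 <= start0 < end0 <= glen):
                    raise ValidationError(
                        f"{locus}: coordinates [{f.start},{f.end}] outside {f.seqid} (length {glen})")
            genes.append(GeneRecord(
                locus_tag=locus, genome_id=f.seqid, start=start0, end=end0,
                strand=f.strand,
                gene_name=(f.attributes.get("gene") or [""])[0],
                product=(f.attributes.get("product") or [""])[0]))
    return genes


def write_gff3(genes: Iterable[GeneRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.genome_id, g.start)):
            attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag}"
            if g.gene_name:
                attrs += f";gene={g.gene_name}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(f"{g.genome_id}\tsim\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t0\t{attrs}\n")


def read_operon_table(path: str, genes: Sequence[GeneRecord] | None = None) -> list[Operon]:
    """Read a DOOR-style operon TSV (operon_id, genome_id, comma-joined locus_tags).

    If ``genes`` is given, membership, strand agreement and 5'->3' ordering
    are validated against the gene records.
    """
    by_tag = {g.locus_tag: g for g in genes} if genes is not None else None
    operons = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            oid, gid, tags_s = line.rstrip("\n").split("\t")
            tags = tuple(tags_s.split(","))
            strand = "+"
            if by_tag is not None:
                members = []
                for t in tags:
                    if t not in by_tag:
                        raise ValidationError(f"operon {oid}: unknown locus_tag {t!r}")
                    members.append(by_tag[t])
                strands = {m.strand for m in members}
                genomes = {m.genome_id for m in members}
                if len(strands) != 1 or genomes != {gid}:
                    raise ValidationError(f"operon {oid}: members disagree on strand/genome")
                strand = strands.pop()
                coords = [m.start for m in members]
                ordered = sorted(coords) if strand == "+" else sorted(coords, reverse=True)
                if coords != ordered:
                    raise ValidationError(f"operon {oid}: gene order inconsistent with coordinates")
            operons.append(Operon(oid, gid, tags, strand))
    return operons


def write_operon_table(operons: Iterable[Operon], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("operon_id\tgenome_id\tlocus_tags\n")
        for op in operons:
            fh.write(f"{op.operon_id}\t{op.genome_id}\t{','.join(op.locus_tags)}\n")


def write_assignments(assignments: Iterable[RegulatoryAssignment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\thit_start\thit_end\tstrand\tscore_bits\twindow_index\t"
                 "target_kind\ttarget_id\tdistance\tnote\n")
        for a in assignments:
            h = a.hit
            fh.write(f"{h.genome_id}\t{h.start}\t{h.end}\t{h.strand}\t{h.score:.4f}\t"
                     f"{h.window_index}\t{a.target_kind}\t{a.target_id or ''}\t"
                     f"{'' if a.distance is None else a.distance}\t{a.note}\n")


def read_assignments(path: str) -> list[RegulatoryAssignment]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            (gid, s, e, st, sc, w, kind, tid, dist, note) = line.rstrip("\n").split("\t")
            hit = RiboswitchHit(gid, int(s), int(e), st, float(sc), int(w))
            out.append(RegulatoryAssignment(
                hit, kind, tid or None, int(dist) if dist else None, note))
    return out
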