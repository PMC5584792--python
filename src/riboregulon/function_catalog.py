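"""Functional classification of riboswitch-regulated genes and phylogenomic profiles.

The catalogue distinguishes diaminopimelate-pathway lysine biosynthesis genes
(lysC, asd, dapA, dapB, dapD, dapH, ddh, dapF, lysA), lysine transporter
genes with their COG families (lysP/gabP = COG0833, lysW = COG1757,
yvsH = COG0531, lysX-lysY = COG0834) and the lysine catabolic pair kal/kce.
Genes whose products are annotated as hypothetical proteins form their own
class; everything else — including pathway-adjacent insertions such as amino
hydrolase, aminotransferase or alanine racemase (alr) — is "other".

The phylogenomic profile is a species x catalogue-gene matrix with cell
states riboswitch_and_gene / gene_only / absent, the machine-readable twin
of the published presence/absence figures, exportable as iTOL binary
datasets (circles for biosynthesis, squares for transporters, stars for
catabolic genes).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .genome_context import GeneRecord, Operon, RegulatoryAssignment, ValidationError

RIBOSWITCH_AND_GENE = "riboswitch_and_gene"
GENE_ONLY = "gene_only"
ABSENT = "absent"

_KIND_SHAPE = {"biosynthesis": "2", "transporter": "1", "catabolic": "3"}  # iTOL codes
_KIND_COLOR = {"biosynthesis": "#1f77b4", "transporter": "#ff7f0e", "catabolic": "#2c2c2c"}


def _norm(name: str) -> str:
    s = name.strip().lower().replace("–", "-").replace("_", " ")
    return re.sub(r"\s+", " ", s)


@dataclass(frozen=True)
class GeneClass:
    kind: str                 # biosynthesis | transporter | catabolic | hypothetical | other
    subtype: str | None = None  # canonical catalogue name (e.g. lysP/gabP)
    cog_id: str | None = None

    def __str__(self) -> str:
        return f"{self.kind}({self.subtype})" if self.subtype else self.kind


@dataclass
class FunctionCatalog:
    """Editable gene-function catalogue (name, class, COG, synonyms)."""

    classes: dict[str, tuple[str, str | None]]   # normalised name -> (kind, cog)
    synonyms: dict[str, str]                     # normalised alias -> canonical name
    canonical: dict[str, str] = field(default_factory=dict)  # normalised -> display name

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "FunctionCatalog":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        classes, synonyms, canonical = {}, {}, {}
        for _, row in df.iterrows():
            key = _norm(row["name"])
            classes[key] = (row["class"], row["cog_id"] or None)
            canonical[key] = row["name"]
            for syn in filter(None, row["synonyms"].split(",")):
                synonyms[_norm(syn)] = key
        cat = cls(classes=classes, synonyms=synonyms, canonical=canonical)
        cat._check_disjoint()
        return cat

    @classmethod
    def default(cls) -> "FunctionCatalog":
        return cls.from_tsv(resources.files("riboregulon.data") / "catalog.tsv")

    def _check_disjoint(self) -> None:
        # synonym targets must exist and each name has exactly one class
        for alias, target in self.synonyms.items():
            if target not in self.classes:
                raise ValidationError(f"synonym {alias!r} points at unknown name {target!r}")
            if alias in self.classes:
                raise ValidationError(f"{alias!r} is both a catalogue name and a synonym")

    def resolve(self, name: str) -> str | None:
        key = _norm(name)
        key = self.synonyms.get(key, key)
        return key if key in self.classes else None

    @property
    def names_by_kind(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for key, (kind, _) in self.classes.items():
            out.setdefault(kind, []).append(self.canonical[key])
        return out


def classify_gene(gene: GeneRecord | str, catalog: FunctionCatalog) -> GeneClass:
    """Classify by gene name, then synonym map, then product keywords.

    The lysP/gabP pair shares COG0833 and is reported with the combined
    subtype label the published figures use.
    """
    if isinstance(gene, GeneRecord):
        name = gene.gene_name or gene.locus_tag
        product = gene.product
    else:
        name, product = gene, ""
    key = catalog.resolve(name)
    if key is not None:
        kind, cog = catalog.classes[key]
        if kind == "transporter":
            sub = "lysP/gabP" if key in ("lysp", "gabp") else catalog.canonical[key]
            return GeneClass("transporter", sub, cog)
        if kind in ("biosynthesis", "catabolic"):
            return GeneClass(kind, None, cog)
        return GeneClass("other", None, cog)
    if _norm(name).startswith("hypothetical") or "hypothetical protein" in product.lower():
        return GeneClass("hypothetical")
    return GeneClass("other")


@dataclass
class OperonComposition:
    total: int
    counts: dict[str, int]
    gene_classes: list[tuple[str, GeneClass]]   # (gene name, class) in operon order


def operon_composition(operon: Operon | Sequence[str],
                       catalog: FunctionCatalog,
                       genes: Mapping[str, GeneRecord] | None = None) -> OperonComposition:
    """Per-class gene counts for an operon, preserving gene order.

    Accepts either an :class:`Operon` (gene names resolved through ``genes``)
    or a plain ordered sequence of gene names as printed in operon tables.
    """
    if isinstance(operon, Operon):
        names: list[str | GeneRecord] = [
            genes[t] if genes and t in genes else t for t in operon.locus_tags]
    else:
        names = list(operon)
    if not names:
        raise ValidationError("empty operon")
    gene_classes = []
    counts: dict[str, int] = {}
    for item in names:
        gc = classify_gene(item, catalog)
        label = item.gene_name or item.locus_tag if isinstance(item, GeneRecord) else item
        gene_classes.append((label, gc))
        counts[gc.kind] = counts.get(gc.kind, 0) + 1
    return OperonComposition(total=len(names), counts=counts, gene_classes=gene_classes)


# ---------------------------------------------------------------------------
# phylogenomic profile


@dataclass
class PhyloProfile:
    species: list[str]                     # tree leaf order
    columns: list[str]                     # catalogue gene names
    column_kinds: dict[str, str]           # column -> class kind
    states: dict[tuple[str, str], str]     # (species, column) -> state
    operon_flag: dict[str, bool] = field(default_factory=dict)

    def state(self, species: str, column: str) -> str:
        return self.states.get((species, column), ABSENT)


def _profile_column(catalog: FunctionCatalog, gc: GeneClass, key: str) -> str | None:
    if gc.kind == "transporter":
        return gc.subtype
    if gc.kind in ("biosynthesis", "catabolic"):
        return catalog.canonical[key]
    return None


def build_profile(assignments: Sequence[RegulatoryAssignment],
                  genes: Sequence[GeneRecord],
                  operons: Sequence[Operon],
                  taxonomy: Mapping[str, str],
                  tree: dendropy.Tree,
                  catalog: FunctionCatalog) -> PhyloProfile:
    """Species x catalogue-gene profile of riboswitch regulation.

    A cell is ``riboswitch_and_gene`` when an assignment targets a gene of
    that column (an operon target marks every catalogued gene the operon
    contains), ``gene_only`` when the species has the gene but no riboswitch
    in front of it, ``absent`` otherwise.
    """
    leaf_species = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = sorted({taxonomy.get(a.hit.genome_id, a.hit.genome_id)
                      for a in assignments if a.target_kind != "none"}
                     - set(leaf_species))
    if missing:
        raise ValidationError(
            "species in assignments missing from tree: " + ", ".join(missing))

    def column_of(gene: GeneRecord) -> str | None:
        gc = classify_gene(gene, catalog)
        key = catalog.resolve(gene.gene_name or gene.locus_tag)
        if key is None:
            return None
        return _profile_column(catalog, gc, key)

    columns: list[str] = []
    column_kinds: dict[str, str] = {}
    for key, (kind, _) in catalog.classes.items():
        if kind not in ("biosynthesis", "transporter", "catabolic"):
            continue
        gc = classify_gene(catalog.canonical[key], catalog)
        col = _profile_column(catalog, gc, key)
        if col is not None and col not in column_kinds:
            columns.append(col)
            column_kinds[col] = kind if kind != "transporter" else "transporter"

    genes_by_tag = {g.locus_tag: g for g in genes}
    operons_by_id = {op.operon_id: op for op in operons}

    states: dict[tuple[str, str], str] = {}
    for g in genes:
        sp = taxonomy.get(g.genome_id, g.genome_id)
        col = column_of(g)
        if col is not None and sp in leaf_species:
            states.setdefault((sp, col), GENE_ONLY)

    operon_flag: dict[str, bool] = {sp: False for sp in leaf_species}
    for a in assignments:
        if a.target_kind == "none":
            continue
        sp = taxonomy.get(a.hit.genome_id, a.hit.genome_id)
        if a.target_kind == "gene":
            targets = [genes_by_tag[a.target_id]] if a.target_id in genes_by_tag else []
        else:
            operon_flag[sp] = True
            op = operons_by_id.get(a.target_id)
            targets = [genes_by_tag[t] for t in (op.locus_tags if op else ())
                       if t in genes_by_tag]
        for g in targets:
            col = column_of(g)
            if col is not None:
                states[(sp, col)] = RIBOSWITCH_AND_GENE
    return PhyloProfile(species=leaf_species, columns=columns,
                        column_kinds=column_kinds, states=states,
                        operon_flag=operon_flag)


def write_profile_tsv(profile: PhyloProfile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("species\toperon\t" + "\t".join(profile.columns) + "\n")
        for sp in profile.species:
            row = [sp, "1" if profile.operon_flag.get(sp) else "0"]
            row += [profile.state(sp, c) for c in profile.columns]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# iTOL export


_STATE_CODE = {RIBOSWITCH_AND_GENE: "1", GENE_ONLY: "0", ABSENT: "-1"}
_CODE_STATE = {v: k for k, v in _STATE_CODE.items()}


def export_itol(profile: PhyloProfile, out_dir: str) -> list[str]:
    """Write one iTOL DATASET_BINARY file per class kind.

    Encoding: 1 = riboswitch and gene present (filled symbol), 0 = gene only
    (outline symbol), -1 = absent (no symbol).  Shapes follow the published
    legends: circles for biosynthesis, squares for transporters, stars for
    catabolic genes.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for kind, shape in _KIND_SHAPE.items():
        cols = [c for c in profile.columns if profile.column_kinds[c] == kind]
        if not cols:
            continue
        path = os.path.join(out_dir, f"itol_{kind}.txt")
        with open(path, "w") as fh:
            fh.write("DATASET_BINARY\nSEPARATOR COMMA\n")
            fh.write(f"DATASET_LABEL,riboswitch {kind} genes\n")
            fh.write(f"COLOR,{_KIND_COLOR[kind]}\n")
            fh.write("FIELD_SHAPES," + ",".join([shape] * len(cols)) + "\n")
            fh.write("FIELD_LABELS," + ",".join(cols) + "\n")
            fh.write("FIELD_COLORS," + ",".join([_KIND_COLOR[kind]] * len(cols)) + "\n")
            fh.write("DATA\n")
            for sp in profile.species:
                codes = [_STATE_CODE[profile.state(sp, c)] for c in cols]
                fh.write(sp.replace(",", "_") + "," + ",".join(codes) + "\n")
        paths.append(path)
    return paths


def parse_itol(path: str) -> dict[tuple[str, str], str]:
    """Recover (species, column) -> state from an emitted iTOL dataset file."""
    states = {}
    cols: list[str] = []
    in_data = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("FIELD_LABELS,"):
                cols = line.split(",")[1:]
            elif line == "DATA":
                in_data = True
            elif in_data and line:
                parts = line.split(",")
                for c, code in zip(cols, parts[1:]):
                    states[(parts[0], c)] = _CODE_STATE[code]
    return states


def load_table1_operons() -> pd.DataFrame:
    """The printed riboswitch-regulated operon table, as packaged fixture."""
    path = resources.files("riboregulon.data") / "table1_operons.tsv"
    df = pd.read_csv(str(path), sep="\t", dtype=str)
    df["genes"] = df["genes"].str.split(",")
    return df
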