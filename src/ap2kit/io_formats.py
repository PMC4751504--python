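"""Readers and writers for the standard formats the pipeline touches.

Coordinate convention: everything internal is 0-based, half-open.  GFF3 is
1-based inclusive and is converted at this boundary, so a feature spanning
GFF columns ``start..end`` has internal length ``end - start + 1``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import gffutils
import pandas as pd
from Bio import SeqIO

from .tree import PhyloTree

__all__ = [
    "SequenceRecord", "Transcript", "GeneModel", "ExpressionTable", "SyntenyBlock",
    "FormatError", "read_fasta", "write_fasta", "read_gff3", "write_gff3",
    "read_expression_table", "write_expression_table", "read_synteny_blocks",
    "write_synteny_blocks", "read_newick", "write_newick", "natural_chrom_key",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class SequenceRecord:
    """One protein (or aligned-protein) sequence.

    ``residues`` is uppercase; seed-alignment records may additionally contain
    the gap character ``-``.
    """

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted, non-overlapping
    protein_id: Optional[str] = None

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    start: int  # 0-based half-open
    end: int
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def protein_ids(self) -> list[str]:
        return [t.protein_id for t in self.transcripts if t.protein_id is not None]


@dataclass
class ExpressionTable:
    """Gene x sample abundance matrix plus per-sample metadata.

    ``values`` is a DataFrame indexed by gene id, columns = sample ids;
    ``metadata`` is indexed by sample id with columns ``condition``,
    ``timepoint_hours`` (may be NaN) and ``replicate``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    units: str = "counts"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        missing = [s for s in self.sample_ids if s not in self.metadata.index]
        if missing:
            raise FormatError(f"samples missing from metadata: {', '.join(missing)}")
        if "condition" not in self.metadata.columns:
            raise FormatError("metadata lacks a 'condition' column")
        if self.metadata.loc[self.sample_ids, "condition"].isna().any():
            raise FormatError("every sample must have a condition")
        if self.units == "counts" and (self.values.to_numpy() < 0).any():
            raise FormatError("negative values in a counts table")


@dataclass
class SyntenyBlock:
    block_id: str
    species_a: str
    species_b: str
    anchor_pairs: list[tuple[str, str]]  # (gene_id_a, gene_id_b)
    region_a: tuple[str, int, int]  # chromosome, start, end (0-based half-open)
    region_b: tuple[str, int, int]

    def __post_init__(self) -> None:
        if not self.anchor_pairs:
            raise FormatError(f"synteny block {self.block_id} has no anchor pairs")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read a (possibly aligned) protein FASTA file.

    Residues are uppercased; record order is preserved.  Duplicate ids and
    text before the first header are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FormatError(f"{path}:{lineno}: expected FASTA header, got {line.strip()!r}")
            break
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), description=desc))
    return records


def write_fasta(records: list[SequenceRecord], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: PathLike) -> list[GeneModel]:
    """Parse gene/mRNA/exon features from a GFF3 file into :class:`GeneModel`s.

    1-based inclusive GFF coordinates are converted to 0-based half-open.
    Exons are sorted by start within each transcript.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique", force=True,
    )
    gene_ids = {f.id for f in db.features_of_type("gene")}
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if gene.end < gene.start:
            raise FormatError(f"gene {gene.id}: end < start")
        g = GeneModel(
            gene_id=gene.id, chromosome=gene.seqid,
            start=gene.start - 1, end=gene.end, strand=gene.strand,
        )
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons = []
            for exon in db.children(mrna, featuretype="exon", order_by="start"):
                if exon.end < exon.start:
                    raise FormatError(f"exon of {mrna.id}: end < start")
                s, e = exon.start - 1, exon.end
                if s < g.start or e > g.end:
                    raise FormatError(
                        f"exon {s}-{e} of transcript {mrna.id} outside gene span of {gene.id}")
                exons.append((s, e))
            exons.sort()
            for (s1, e1), (s2, _) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise FormatError(f"overlapping exons in transcript {mrna.id}")
            protein_id = mrna.attributes.get("protein_id", [None])[0]
            g.transcripts.append(Transcript(transcript_id=mrna.id, exons=exons, protein_id=protein_id))
        models.append(g)
    # orphan mRNAs: mRNA features whose Parent is not a known gene
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        if not parents or not any(p in gene_ids for p in parents):
            raise FormatError(f"mRNA {mrna.id} has no gene parent")
    return models


def write_gff3(models: list[GeneModel], path: PathLike, source: str = "ap2kit") -> None:
    """Write gene models as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            attrs = f"ID={g.gene_id}"
            fh.write("\t".join([g.chromosome, source, "gene", str(g.start + 1), str(g.end),
                                ".", g.strand, ".", attrs]) + "\n")
            for t in g.transcripts:
                attrs = f"ID={t.transcript_id};Parent={g.gene_id}"
                if t.protein_id:
                    attrs += f";protein_id={t.protein_id}"
                t_start = min(s for s, _ in t.exons) if t.exons else g.start
                t_end = max(e for _, e in t.exons) if t.exons else g.end
                fh.write("\t".join([g.chromosome, source, "mRNA", str(t_start + 1), str(t_end),
                                    ".", g.strand, ".", attrs]) + "\n")
                for i, (s, e) in enumerate(t.exons, start=1):
                    attrs = f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"
                    fh.write("\t".join([g.chromosome, source, "exon", str(s + 1), str(e),
                                        ".", g.strand, ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression_table(path: PathLike, metadata_path: PathLike, units: str = "counts") -> ExpressionTable:
    """Read a gene x sample TSV and its sample-metadata sidecar TSV."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    metadata.index = metadata.index.astype(str)
    table = ExpressionTable(values=values, metadata=metadata, units=units)
    table.validate()
    return table


def write_expression_table(table: ExpressionTable, path: PathLike, metadata_path: Optional[PathLike] = None) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene_id")
    if metadata_path is not None:
        table.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Synteny blocks
# ---------------------------------------------------------------------------

_SYNTENY_COLS = ["block_id", "species_a", "chrom_a", "start_a", "end_a", "gene_a",
                 "species_b", "chrom_b", "start_b", "end_b", "gene_b"]


def read_synteny_blocks(path: PathLike) -> list[SyntenyBlock]:
    """Read synteny blocks from a TSV with one row per anchor pair."""
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in
                                            ["block_id", "species_a", "chrom_a", "gene_a",
                                             "species_b", "chrom_b", "gene_b"]})
    missing = [c for c in _SYNTENY_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"synteny table lacks columns: {', '.join(missing)}")
    blocks = []
    for block_id, rows in df.groupby("block_id", sort=False):
        r0 = rows.iloc[0]
        blocks.append(SyntenyBlock(
            block_id=str(block_id),
            species_a=r0["species_a"], species_b=r0["species_b"],
            anchor_pairs=[(a, b) for a, b in zip(rows["gene_a"], rows["gene_b"])],
            region_a=(r0["chrom_a"], int(r0["start_a"]), int(r0["end_a"])),
            region_b=(r0["chrom_b"], int(r0["start_b"]), int(r0["end_b"])),
        ))
    return blocks


def write_synteny_blocks(blocks: list[SyntenyBlock], path: PathLike) -> None:
    rows = []
    for b in blocks:
        for ga, gb in b.anchor_pairs:
            rows.append([b.block_id, b.species_a, b.region_a[0], b.region_a[1], b.region_a[2], ga,
                         b.species_b, b.region_b[0], b.region_b[1], b.region_b[2], gb])
    pd.DataFrame(rows, columns=_SYNTENY_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree: PhyloTree, path: PathLike) -> None:
    labels = tree.leaf_labels()
    if len(labels) != len(set(labels)):
        raise FormatError("tree has duplicate leaf labels")
    with open(path, "w") as fh:
        fh.write(tree.to_newick())


def read_newick(path: PathLike) -> PhyloTree:
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read())


# ---------------------------------------------------------------------------
# Misc
# ---------------------------------------------------------------------------

def natural_chrom_key(name: str):
    """Sort key placing 'Bd2' before 'Bd10' (trailing-integer natural order)."""
    m = re.search(r"(\d+)$", name)
    if m:
        return (0, name[: m.start()], int(m.group(1)))
    return (1, name, 0)
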