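"""Readers and writers for the external formats the pipeline touches.

Every other module operates on the in-memory domain types defined here:
:class:`ProteinRecord`, :class:`GeneModel`, :class:`CtTable`, plus the
shared 1-based-inclusive :class:`Span` interval. All genomic and protein
coordinates throughout the package are 1-based inclusive (the GFF3
convention); the protein-to-CDS converters live here so the off-by-one
surface is a single audited spot.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when a parsed record violates a domain-type invariant."""


@dataclass(frozen=True, order=True)
class Span:
    """Closed interval, 1-based inclusive (genomic or protein coordinates)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"invalid span [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def codon_span(protein_pos: int) -> Span:
    """CDS nucleotides (1-based) covered by protein position ``p``: 3p-2..3p."""
    return Span(3 * protein_pos - 2, 3 * protein_pos)


def junction_codon(coding_offset: int) -> int:
    """Protein position owning a splice junction after ``coding_offset`` CDS nt.

    A phase-0 junction sits exactly between two codons and is assigned to the
    codon on its 3' side; junctions inside a codon belong to that codon.
    """
    if coding_offset < 0:
        raise ValidationError("coding offset must be >= 0")
    return coding_offset // 3 + 1


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence (uppercase 20-letter alphabet plus X)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record with empty id")
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValidationError(
                f"protein {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A protein-coding gene: CDS segments in translation order.

    ``cds_segments`` are genomic intervals, 1-based inclusive, listed in
    translation order: ascending genomic coordinates on the + strand,
    descending on the - strand.
    """

    gene_id: str
    chromosome: str
    strand: str
    cds_segments: list[Span]
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if not self.cds_segments:
            raise ValidationError(f"gene {self.gene_id}: no CDS segments")
        starts = [s.start for s in self.cds_segments]
        expected = sorted(starts, reverse=self.strand == "-")
        if starts != expected:
            raise ValidationError(
                f"gene {self.gene_id}: CDS segments not in translation order "
                f"for strand {self.strand}"
            )
        ordered = sorted(self.cds_segments)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"gene {self.gene_id}: overlapping CDS segments {a} and {b}"
                )
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"gene {self.gene_id}: CDS length {self.cds_length} "
                "not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(len(s) for s in self.cds_segments)

    @property
    def span(self) -> Span:
        return Span(
            min(s.start for s in self.cds_segments),
            max(s.end for s in self.cds_segments),
        )


@dataclass
class CtTable:
    """Replicate-level qPCR Ct measurements.

    ``data`` holds one row per (gene_id, condition_id, replicate) with a
    ``ct`` column in cycles. The reference (housekeeping) gene must be
    measured in every condition, and every (gene, condition) cell must carry
    the same number of replicates.
    """

    data: pd.DataFrame
    reference_gene_id: str
    calibrator_condition_id: str

    REQUIRED = ("gene_id", "condition_id", "replicate", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"Ct table missing columns: {missing}")
        counts = self.data.groupby(["gene_id", "condition_id"]).size()
        if counts.nunique() > 1:
            raise ValidationError(
                "unequal replicate counts across (gene, condition) cells: "
                f"{sorted(counts.unique())}"
            )
        conds = set(self.data["condition_id"])
        ref_conds = set(
            self.data.loc[self.data.gene_id == self.reference_gene_id, "condition_id"]
        )
        if conds - ref_conds:
            raise ValidationError(
                f"reference gene {self.reference_gene_id!r} missing in "
                f"conditions {sorted(conds - ref_conds)}"
            )
        if self.calibrator_condition_id not in conds:
            raise ValidationError(
                f"calibrator condition {self.calibrator_condition_id!r} absent"
            )

    @property
    def genes(self) -> list[str]:
        return [g for g in self.data.gene_id.unique() if g != self.reference_gene_id]

    @property
    def conditions(self) -> list[str]:
        return list(self.data.condition_id.unique())

    @property
    def n_replicates(self) -> int:
        return int(self.data.groupby(["gene_id", "condition_id"]).size().iloc[0])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects (file order)."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        records.append(ProteinRecord(rec.id, seq))
    return records


def write_fasta(records, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_genome_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a genome FASTA as {chromosome: uppercase sequence}."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"{path}: duplicate chromosome {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_genome_fasta(genome: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()),
            fh,
            "fasta",
        )


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Assemble :class:`GeneModel` objects from GFF3 CDS features.

    CDS features must carry a ``Parent`` gene id; minus-strand genes have
    their segments reversed into translation order. Genes whose total CDS
    length is not divisible by 3 raise :class:`ValidationError`.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    by_gene: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent")
        if not parents:
            raise FormatError(f"{path}: CDS at {cds.start} has no Parent attribute")
        gene_id = parents[0]
        entry = by_gene.setdefault(
            gene_id,
            {"chromosome": cds.seqid, "strand": cds.strand, "segments": [],
             "protein_id": cds.attributes.get("protein_id", [""])[0]},
        )
        entry["segments"].append(Span(cds.start, cds.end))
    models = []
    for gene_id, entry in by_gene.items():
        segments = sorted(entry["segments"], reverse=entry["strand"] == "-")
        models.append(
            GeneModel(
                gene_id=gene_id,
                chromosome=entry["chromosome"],
                strand=entry["strand"],
                cds_segments=segments,
                protein_id=entry["protein_id"] or gene_id,
            )
        )
    return models


def write_gene_models(models, path: str | os.PathLike) -> None:
    """Write gene + CDS features as GFF3 (round-trips through read)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = m.span
            fh.write(
                f"{m.chromosome}\tbzipkit\tgene\t{span.start}\t{span.end}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}\n"
            )
            for seg in sorted(m.cds_segments):
                fh.write(
                    f"{m.chromosome}\tbzipkit\tCDS\t{seg.start}\t{seg.end}\t.\t"
                    f"{m.strand}\t.\tParent={m.gene_id};protein_id={m.protein_id}\n"
                )


# ---------------------------------------------------------------------------
# Ct tables


def read_ct_table(
    path: str | os.PathLike,
    reference_gene_id: str,
    calibrator_condition_id: str,
) -> CtTable:
    """Read a tab-separated Ct table (gene_id, condition_id, replicate, ct)."""
    df = pd.read_csv(path, sep="\t")
    return CtTable(df, reference_gene_id, calibrator_condition_id)


def write_ct_table(table: CtTable, path: str | os.PathLike) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick trees (dendropy containers)


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a single-line Newick string with support labels."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_internal_node_labels=False,
    )
    return s.strip()


def read_newick(newick: str, taxon_namespace=None) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick,
        schema="newick",
        taxon_namespace=taxon_namespace,
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def read_alignment_fasta(path: str | os.PathLike):
    """Read an aligned FASTA; returns (ids, rows). Validates equal lengths."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if rows and len({len(r) for r in rows}) != 1:
        raise FormatError(f"{path}: aligned rows have unequal lengths")
    return ids, rows
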