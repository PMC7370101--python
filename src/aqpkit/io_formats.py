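"""Readers and writers for the external representations the pipeline touches.

Protein FASTA, GFF3 gene models, FPKM expression tables with a replicate
design, and the two machine-readable reference tables bundled with the
package (the gene inventory and the substrate-specificity pattern table).

All genomic coordinates are 0-based half-open internally; GFF3 I/O converts
from the 1-based closed convention at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "GeneInventoryRow",
    "GeneModel",
    "ExpressionMatrix",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_expression_tsv",
    "load_sdp_table",
    "load_gene_inventory",
]

#: The 20 proteinogenic residues plus X for an undetermined residue.
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_ALPHABET = AMINO_ACIDS | {"X"}

SUBFAMILIES = ("PIP", "TIP", "NIP", "SIP", "XIP")

_GENE_NAME_RE = re.compile(
    r"^(?P<species>[A-Z][a-z]{0,2})?"
    r"(?P<subfamily>PIP|TIP|NIP|SIP|XIP)"
    r"(?P<group>\d+);(?P<isoform>\d+)"
    r"(?P<variant>[αβ])?$"
)


class FastaError(ValueError):
    """Malformed FASTA input (bad header, empty sequence, duplicate id)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One candidate protein sequence.

    Parameters
    ----------
    id : str
        Unique identifier within a collection.
    sequence : str
        Uppercase amino-acid string over the 20-letter alphabet plus ``X``.
    species_tag : str, optional
        Free-form species label (e.g. ``"Nt"``).
    splice_variant : str, optional
        Splice-variant suffix such as ``"α"`` or ``"β"``.
    """

    id: str
    sequence: str
    species_tag: str | None = None
    splice_variant: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        bad = set(self.sequence) - ALLOWED_ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: invalid residues {sorted(bad)!r} "
                "(expected the 20-letter amino-acid alphabet plus X)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneInventoryRow:
    """One protein row of the bundled gene inventory table."""

    gene_name: str
    accession: str
    pi: float
    mw_kda: float
    aa_count: int
    localization_labels: frozenset[str]
    subfamily: str = field(init=False)
    group: int = field(init=False)
    isoform: int = field(init=False)
    variant: str | None = field(init=False)

    def __post_init__(self) -> None:
        if self.aa_count <= 0:
            raise ValueError(f"{self.gene_name}: aa_count must be positive")
        m = _GENE_NAME_RE.match(self.gene_name)
        if m is None:
            raise ValueError(f"unparseable gene name: {self.gene_name!r}")
        object.__setattr__(self, "subfamily", m.group("subfamily"))
        object.__setattr__(self, "group", int(m.group("group")))
        object.__setattr__(self, "isoform", int(m.group("isoform")))
        object.__setattr__(self, "variant", m.group("variant"))

    @property
    def locus_name(self) -> str:
        """Gene name with any splice-variant suffix removed."""
        if self.variant:
            return self.gene_name[: -len(self.variant)]
        return self.gene_name


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one mRNA on the gene's own coordinate system.

    ``exons`` are 0-based half-open intervals, sorted and non-overlapping.
    """

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(
                    f"{self.gene_id}: empty or inverted exon ({start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"{self.gene_id}: exons overlap or are unsorted at {start}"
                )
            prev_end = end

    @property
    def span(self) -> int:
        return self.exons[-1][1] - self.exons[0][0]


class ExpressionMatrix:
    """FPKM values per gene x sample with a sample -> (condition, replicate) design.

    Values are non-negative; every sample column appears exactly once in the
    design and every condition has at least one replicate.
    """

    def __init__(self, values: pd.DataFrame, design: Mapping[str, tuple[str, int]]):
        if values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        missing = set(values.columns) - set(design)
        if missing:
            raise ValueError(f"samples absent from design: {sorted(missing)}")
        extra = set(design) - set(values.columns)
        if extra:
            raise ValueError(f"design samples absent from matrix: {sorted(extra)}")
        if values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        self.values = values.astype(float)
        self.design = dict(design)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for cond, _rep in self.design.values():
            seen.setdefault(cond, None)
        return list(seen)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.design[s][0] == condition]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and trailing ``*`` stop characters stripped.
    Duplicate ids and empty sequences are rejected.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise FastaError(f"{path}: FASTA entry with empty header")
        if entry.id in seen:
            raise FastaError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper().rstrip("*")
        if not seq:
            raise FastaError(f"{path}: record {entry.id!r} has an empty sequence")
        try:
            records.append(ProteinRecord(id=entry.id, sequence=seq))
        except ValueError as exc:
            raise FastaError(str(exc)) from exc
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped protein FASTA."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3, one :class:`GeneModel` per mRNA.

    Exon coordinates are converted from GFF3 1-based closed intervals to
    0-based half-open and sorted by start. An exon whose ``Parent`` does not
    resolve to an mRNA raises a structural error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    models: list[GeneModel] = []
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents or not any(p in mrna_ids for p in parents):
            raise ValueError(
                f"{path}: exon at {exon.start}-{exon.end} has no resolvable mRNA parent"
            )
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(mrna, featuretype="exon")
        )
        if not exons:
            raise ValueError(f"{path}: mRNA {mrna.id!r} has no exons")
        models.append(GeneModel(gene_id=mrna.id, strand=mrna.strand, exons=tuple(exons)))
    return models


def to_gff3_interval(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval back to GFF3 1-based closed."""
    return start + 1, end


def write_gff3(models: Iterable[GeneModel], path: str | Path, seqid: str = "chr1") -> None:
    """Write gene models as GFF3 (gene, mRNA and exon features).

    The mRNA feature carries the model's gene_id, so reading the file back
    reproduces the models; coordinates convert to 1-based closed.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            g_start, g_end = to_gff3_interval(m.exons[0][0], m.exons[-1][1])
            gene_id = f"{m.gene_id}.gene"
            fh.write(
                f"{seqid}\taqpkit\tgene\t{g_start}\t{g_end}\t.\t{m.strand}\t.\tID={gene_id}\n"
            )
            fh.write(
                f"{seqid}\taqpkit\tmRNA\t{g_start}\t{g_end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id};Parent={gene_id}\n"
            )
            for k, (start, end) in enumerate(m.exons, start=1):
                s, e = to_gff3_interval(start, end)
                fh.write(
                    f"{seqid}\taqpkit\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.exon{k};Parent={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Expression tables


def read_expression_tsv(path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read an FPKM matrix (gene id column + numeric sample columns) and a
    three-column design TSV (sample, condition, replicate)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    design_df = pd.read_csv(design_path, sep="\t")
    expected = {"sample", "condition", "replicate"}
    if not expected.issubset(design_df.columns):
        raise ValueError(
            f"{design_path}: design file must have columns {sorted(expected)}"
        )
    design = {
        str(row["sample"]): (str(row["condition"]), int(row["replicate"]))
        for _, row in design_df.iterrows()
    }
    if len(design) != len(design_df):
        raise ValueError(f"{design_path}: duplicate sample in design")
    return ExpressionMatrix(values, design)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path, design_path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")
    rows = [
        {"sample": s, "condition": c, "replicate": r}
        for s, (c, r) in matrix.design.items()
    ]
    pd.DataFrame(rows).to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Bundled reference tables


def _data_text(name: str) -> str:
    return resources.files("aqpkit.data").joinpath(name).read_text(encoding="utf-8")


def load_sdp_table():
    """Load the bundled substrate-specificity pattern table.

    Returns the eight substrate rows (Bo, CO2, H2O2, NH3, Si, U, As, Sb) as
    :class:`~aqpkit.substrate_prediction.SdpPattern` objects. Pattern lengths
    are validated structurally (4 / 10 / 11 / 5 positions) so a transcription
    error fails fast.
    """
    from aqpkit.substrate_prediction import SdpPattern, compile_pattern

    rows = []
    lines = _data_text("sdp_patterns.tsv").strip().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        rec = dict(zip(header, line.split("\t")))
        roster_cell = rec["roster"].strip()
        if roster_cell == "-":
            roster: tuple[str, ...] = ()
        else:
            roster = tuple(tok.strip() for tok in roster_cell.split(","))
        rows.append(
            SdpPattern(
                substrate=rec["substrate"],
                arR_classes=compile_pattern(rec["arR"]),
                lb_classes=compile_pattern(rec["lb"]),
                le_classes=compile_pattern(rec["le"]),
                fp_classes=compile_pattern(rec["fp"]),
                printed_roster=roster,
            )
        )
    expected = ["Bo", "CO2", "H2O2", "NH3", "Si", "U", "As", "Sb"]
    got = [r.substrate for r in rows]
    if got != expected:
        raise ValueError(f"pattern table integrity: substrates {got} != {expected}")
    return rows


def load_gene_inventory() -> list[GeneInventoryRow]:
    """Load the bundled gene inventory (90 protein rows over 88 gene loci)."""
    lines = _data_text("gene_inventory.tsv").strip().splitlines()
    header = lines[0].split("\t")
    rows = []
    for line in lines[1:]:
        rec = dict(zip(header, line.split("\t")))
        rows.append(
            GeneInventoryRow(
                gene_name=rec["gene_name"],
                accession=rec["accession"],
                pi=float(rec["pi"]),
                mw_kda=float(rec["mw_kda"]),
                aa_count=int(rec["aa_count"]),
                localization_labels=frozenset(rec["localization"].split(",")),
            )
        )
    if len(rows) != 90:
        raise ValueError(f"gene inventory integrity: expected 90 rows, got {len(rows)}")
    return rows
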