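"""Intron/exon structure summaries derived from gene models."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from aqpkit.io_formats import GeneModel

__all__ = ["StructureSummary", "summarize_structure", "structure_table"]

#: Introns at least this long (bp) are flagged as unusually long.
DEFAULT_LONG_INTRON = 10_000


@dataclass(frozen=True)
class StructureSummary:
    gene_id: str
    exon_count: int
    intron_count: int
    intron_lengths: tuple[int, ...]
    long_intron_flags: tuple[int, ...]  # indices into intron_lengths

    def __post_init__(self) -> None:
        if self.intron_count != self.exon_count - 1:
            raise ValueError(f"{self.gene_id}: intron_count != exon_count - 1")
        if len(self.intron_lengths) != self.intron_count:
            raise ValueError(f"{self.gene_id}: intron length list inconsistent")


def summarize_structure(
    model: GeneModel, long_threshold: int = DEFAULT_LONG_INTRON
) -> StructureSummary:
    """Introns are the gaps between consecutive exons (half-open arithmetic);
    those at least ``long_threshold`` bp are flagged."""
    lengths = tuple(
        nxt[0] - prev[1] for prev, nxt in zip(model.exons, model.exons[1:])
    )
    flags = tuple(i for i, ln in enumerate(lengths) if ln >= long_threshold)
    return StructureSummary(
        gene_id=model.gene_id,
        exon_count=len(model.exons),
        intron_count=len(lengths),
        intron_lengths=lengths,
        long_intron_flags=flags,
    )


def structure_table(
    models: Sequence[GeneModel],
    long_threshold: int = DEFAULT_LONG_INTRON,
    collapse_gene: bool = True,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Per-gene structure summaries plus the distribution of intron counts.

    When several mRNAs share a gene id prefix (``gene.mrna``), the mRNA with
    the most exons represents the gene (one structure reported per gene).
    Returns (table sorted by gene id, histogram {intron_count: n_genes}).
    """
    if not models:
        raise ValueError("at least one gene model required")
    summaries = [summarize_structure(m, long_threshold) for m in models]
    if collapse_gene:
        by_gene: dict[str, StructureSummary] = {}
        for s in summaries:
            gene = s.gene_id.split(".")[0]
            if gene not in by_gene or s.exon_count > by_gene[gene].exon_count:
                by_gene[gene] = s
        summaries = list(by_gene.values())
    summaries.sort(key=lambda s: s.gene_id)
    table = pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in summaries],
            "exon_count": [s.exon_count for s in summaries],
            "intron_count": [s.intron_count for s in summaries],
            "intron_lengths": [",".join(map(str, s.intron_lengths)) for s in summaries],
            "n_long_introns": [len(s.long_intron_flags) for s in summaries],
        }
    )
    histogram: dict[int, int] = {}
    for s in summaries:
        histogram[s.intron_count] = histogram.get(s.intron_count, 0) + 1
    return table, dict(sorted(histogram.items()))
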