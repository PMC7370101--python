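"""Subfamily and group assignment by nearest annotated reference.

Each record is aligned globally (Needleman-Wunsch, BLOSUM62, affine gaps
open 10 / extend 1) against a set of annotated reference templates, one per
subfamily-group. The best reference by normalized identity over aligned
non-gap columns determines the subfamily (PIP/TIP/NIP/SIP/XIP) and group;
a record is classified only when identity reaches the threshold over enough
aligned columns. A neighbor-joining tree on pairwise p-distances can be
emitted for visual inspection of the family structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from aqpkit.io_formats import ProteinRecord

__all__ = [
    "POSITION_NAMES",
    "ReferenceTemplate",
    "SubfamilyCall",
    "PairwiseAlignment",
    "align_global",
    "identity_stats",
    "classify_subfamily",
    "build_nj_tree",
]

#: Annotated position names every reference template must carry: the ar/R
#: filter residues from TM2, TM5 and loop E, the five Froger positions, and
#: the Asn of each NPA motif.
POSITION_NAMES = (
    "H2", "H5", "LE1", "LE2",
    "P1", "P2", "P3", "P4", "P5",
    "NPA1_N", "NPA2_N",
)


@dataclass(frozen=True)
class ReferenceTemplate:
    """Annotated reference sequence for one subfamily-group."""

    id: str
    subfamily: str
    group: int
    sequence: str
    positions: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = set(POSITION_NAMES) - set(self.positions)
        if missing:
            raise ValueError(f"{self.id}: missing annotated positions {sorted(missing)}")
        for name, idx in self.positions.items():
            if not 0 <= idx < len(self.sequence):
                raise ValueError(f"{self.id}: position {name} index {idx} out of bounds")
        for name in ("NPA1_N", "NPA2_N"):
            if self.sequence[self.positions[name]] != "N":
                raise ValueError(f"{self.id}: residue at {name} is not Asn")

    def as_record(self) -> ProteinRecord:
        return ProteinRecord(id=self.id, sequence=self.sequence)


@dataclass(frozen=True)
class SubfamilyCall:
    record_id: str
    subfamily: str | None
    group: int | None
    best_reference: str | None
    score: float
    status: str


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment as two gapped strings plus the raw score."""

    a: str
    b: str
    score: float

    def columns(self):
        return zip(self.a, self.b)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner

_ALIGNER = _make_aligner()


def align_global(a: str, b: str) -> PairwiseAlignment:
    """Needleman-Wunsch global alignment, BLOSUM62, affine gaps 10/1.

    Deterministic: of the co-optimal alignments the first in Biopython's
    fixed traceback order is returned.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alignments = _ALIGNER.align(a, b)
    best = alignments[0]
    return PairwiseAlignment(a=str(best[0]), b=str(best[1]), score=best.score)


def identity_stats(aln: PairwiseAlignment) -> tuple[int, int]:
    """(matches, aligned non-gap columns) of a pairwise alignment."""
    matches = columns = 0
    for x, y in aln.columns():
        if x != "-" and y != "-":
            columns += 1
            if x == y:
                matches += 1
    return matches, columns


def classify_subfamily(
    record: ProteinRecord,
    references: Sequence[ReferenceTemplate],
    min_identity: float = 0.35,
    min_columns: int = 150,
) -> SubfamilyCall:
    """Assign subfamily/group from the nearest reference by normalized identity."""
    if not references:
        raise ValueError("reference set must not be empty")
    best_ref = None
    best_identity = -1.0
    for ref in references:
        aln = align_global(record.sequence, ref.sequence)
        matches, columns = identity_stats(aln)
        identity = matches / columns if columns else 0.0
        if identity > best_identity or (
            identity == best_identity and best_ref is not None and ref.id < best_ref[0].id
        ):
            best_ref = (ref, columns)
            best_identity = identity
    ref, columns = best_ref
    if best_identity >= min_identity and columns >= min_columns:
        return SubfamilyCall(
            record_id=record.id,
            subfamily=ref.subfamily,
            group=ref.group,
            best_reference=ref.id,
            score=best_identity,
            status="classified",
        )
    return SubfamilyCall(
        record_id=record.id,
        subfamily=None,
        group=None,
        best_reference=ref.id,
        score=best_identity,
        status="unclassified",
    )


def p_distance(a: str, b: str) -> float:
    """Proportion of mismatching aligned non-gap columns under global alignment."""
    matches, columns = identity_stats(align_global(a, b))
    if columns == 0:
        return 1.0
    return 1.0 - matches / columns


def build_nj_tree(records: Sequence[ProteinRecord]) -> str:
    """Neighbor-joining tree on pairwise p-distances, as a Newick string.

    Negative branch lengths produced by the NJ agglomeration are clamped to
    zero. Leaf labels are the input record ids.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(records) < 3:
        raise ValueError("neighbor joining requires at least 3 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    n = len(records)
    dm = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = p_distance(records[i].sequence, records[j].sequence)
            dm[i][j] = dm[j][i] = d
    tree = nj(DistanceMatrix(dm, ids))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    out = StringIO()
    tree.write(out, format="newick")
    return out.getvalue().strip()
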