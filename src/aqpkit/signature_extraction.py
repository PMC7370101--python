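"""Extraction of selectivity signatures from anchored, classified records.

A protein's signature comprises the four ar/R filter residues
(H2, H5, LE1, LE2), the five Froger positions (P1-P5), and the two
NPA-region strings: a 10-mer around the loop-B motif and an 11-mer around
the loop-E motif.

Coordinates are derived two ways. The NPA-region windows and the LE1/LE2
positions are fixed offsets from the anchored NPA asparagines: the loop-B
window is [NPA1-5, NPA1+5), the loop-E window [NPA2-4, NPA2+7), and
LE1/LE2 sit at NPA2-3 and NPA2+3 (the offsets that place the canonical PIP
exemplar strings SGGHINPAVT and GTGINPARSLG on their printed frames). H2,
H5 and P1-P5 have no reliable sequence-local rule and are transferred from
an annotated reference template through a global alignment. Where both
routes resolve LE1/LE2 and disagree, the NPA-relative value wins and the
conflict is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from aqpkit.io_formats import ProteinRecord
from aqpkit.sequence_annotation import NpaAnchor
from aqpkit.subfamily_classification import ReferenceTemplate, align_global

__all__ = [
    "SignatureSet",
    "LB_OFFSETS",
    "LE_OFFSETS",
    "extract_npa_regions",
    "transfer_positions",
    "extract_signature",
    "group_by_signature",
]

logger = logging.getLogger(__name__)

#: Loop-B window relative to the anchored Asn of the first NPA motif.
LB_OFFSETS = (-5, 5)
#: Loop-E window relative to the anchored Asn of the second NPA motif.
LE_OFFSETS = (-4, 7)
#: LE1 / LE2 offsets from the second NPA Asn.
LE1_OFFSET = -3
LE2_OFFSET = 3

#: Placeholder residue used in signature strings at unresolved positions.
UNRESOLVED = "?"


@dataclass(frozen=True)
class SignatureSet:
    """The extracted selectivity signature of one protein.

    ``coords`` maps position names to 0-based indices; ``flags`` lists
    unresolved positions as ``position_unresolved:<name>``. When no flags are
    present the component strings have lengths exactly 4 / 5 / 10 / 11 and
    every residue equals the record residue at its stored coordinate.
    """

    record_id: str
    arR: str
    froger: str
    lb_region: str
    le_region: str
    coords: Mapping[str, int]
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.flags:
            lengths = (len(self.arR), len(self.froger), len(self.lb_region), len(self.le_region))
            if lengths != (4, 5, 10, 11):
                raise ValueError(
                    f"{self.record_id}: component lengths {lengths} != (4, 5, 10, 11)"
                )


def extract_npa_regions(
    record: ProteinRecord, anchors: tuple[NpaAnchor, NpaAnchor]
) -> tuple[str | None, str | None]:
    """The loop-B 10-mer and loop-E 11-mer around the anchored NPA motifs.

    Returns ``None`` for a window exceeding the sequence bounds.
    """
    seq = record.sequence
    b, e = anchors
    lb_start, lb_end = b.n_index + LB_OFFSETS[0], b.n_index + LB_OFFSETS[1]
    le_start, le_end = e.n_index + LE_OFFSETS[0], e.n_index + LE_OFFSETS[1]
    lb = seq[lb_start:lb_end] if lb_start >= 0 and lb_end <= len(seq) else None
    le = seq[le_start:le_end] if le_start >= 0 and le_end <= len(seq) else None
    return lb, le


def transfer_positions(
    record: ProteinRecord, template: ReferenceTemplate
) -> dict[str, int | None]:
    """Map the template's annotated positions onto the record via alignment.

    Each annotated template index maps to the record residue aligned to that
    column; a position aligned to a gap maps to ``None``.
    """
    aln = align_global(record.sequence, template.sequence)
    template_to_record: dict[int, int | None] = {}
    ri = ti = 0
    for rx, tx in aln.columns():
        if tx != "-":
            template_to_record[ti] = ri if rx != "-" else None
            ti += 1
        if rx != "-":
            ri += 1
    return {name: template_to_record.get(idx) for name, idx in template.positions.items()}


def extract_signature(
    record: ProteinRecord,
    anchors: tuple[NpaAnchor, NpaAnchor],
    template: ReferenceTemplate,
) -> SignatureSet:
    """Assemble the full signature of one record.

    LE1/LE2 come from NPA-relative offsets (authoritative), H2/H5/P1-P5 from
    template transfer; the NPA-region strings from the anchor windows.
    Unresolved positions are flagged rather than raised.
    """
    seq = record.sequence
    b, e = anchors
    flags: set[str] = set()
    coords: dict[str, int] = {"NPA1_N": b.n_index, "NPA2_N": e.n_index}

    lb, le = extract_npa_regions(record, anchors)
    if lb is None:
        flags.add("position_unresolved:LB_region")
        lb = UNRESOLVED * 10
    if le is None:
        flags.add("position_unresolved:LE_region")
        le = UNRESOLVED * 11

    transferred = transfer_positions(record, template)

    def resolve(name: str, npa_relative: int | None = None) -> str:
        idx = npa_relative
        if idx is not None and not (0 <= idx < len(seq)):
            idx = None
        if idx is None:
            idx = transferred.get(name)
        if idx is None:
            flags.add(f"position_unresolved:{name}")
            return UNRESOLVED
        coords[name] = idx
        return seq[idx]

    le1 = resolve("LE1", e.n_index + LE1_OFFSET)
    le2 = resolve("LE2", e.n_index + LE2_OFFSET)
    for name in ("LE1", "LE2"):
        t_idx = transferred.get(name)
        if t_idx is not None and name in coords and t_idx != coords[name]:
            if seq[t_idx] != seq[coords[name]]:
                logger.warning(
                    "%s: %s conflict, NPA-relative %r at %d vs transferred %r at %d; "
                    "keeping NPA-relative",
                    record.id, name, seq[coords[name]], coords[name], seq[t_idx], t_idx,
                )
    h2 = resolve("H2")
    h5 = resolve("H5")
    fp = "".join(resolve(f"P{i}") for i in range(1, 6))

    return SignatureSet(
        record_id=record.id,
        arR=h2 + h5 + le1 + le2,
        froger=fp,
        lb_region=lb,
        le_region=le,
        coords=coords,
        flags=frozenset(flags),
    )


def group_by_signature(
    signatures: Iterable[SignatureSet], component: str = "arR"
) -> dict[str, list[str]]:
    """Partition records by exact equality of one signature component.

    ``component`` is ``"arR"`` or ``"froger"``. Groups are keyed by the
    component string and ordered by decreasing size, ties lexicographically;
    flagged signatures collect in an ``"unresolved"`` bin appended last.
    """
    if component not in {"arR", "froger"}:
        raise ValueError("component must be 'arR' or 'froger'")
    groups: dict[str, list[str]] = {}
    unresolved: list[str] = []
    for sig in signatures:
        if sig.flags:
            unresolved.append(sig.record_id)
        else:
            groups.setdefault(getattr(sig, component), []).append(sig.record_id)
    ordered = dict(sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0])))
    if unresolved:
        ordered["unresolved"] = unresolved
    return ordered
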