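"""Per-sequence structural annotation of MIP candidates.

Transmembrane segmentation by Kyte-Doolittle sliding-window hydropathy,
tolerant NPA-motif anchoring in loops B and E, a completeness screen that
flags pseudogene-like fragments, and physicochemical properties (average
molecular weight, isoelectric point).

MIP channels have six TM helices and two NPA (Asn-Pro-Ala) motifs, one in
loop B between TM2 and TM3 and one in loop E between TM5 and TM6. The third
residue of the motif varies across subfamilies (threonine or leucine in
SIPs, valine in XIPs and some NIPs), so anchoring tolerates a configurable
set of third residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

from aqpkit.io_formats import ProteinRecord

__all__ = [
    "KYTE_DOOLITTLE",
    "NPA_THIRD_RESIDUES",
    "TmSegmentation",
    "NpaAnchor",
    "ScreenVerdict",
    "MwResult",
    "AnchoringError",
    "predict_tm_segments",
    "find_npa_anchors",
    "screen_record",
    "compute_mw",
    "compute_pi",
]

#: Kyte-Doolittle hydropathy index; X (undetermined) scored neutral.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

#: Tolerated third residues of the N-P-x motif: alanine plus every variant
#: observed in plant MIPs (T, L, V, S) and conservative neighbours.
NPA_THIRD_RESIDUES = frozenset("ATLVSCGIM")

# Third-residue preference used to rank candidate motifs.
_THIRD_SCORE = {"A": 2, "T": 1, "V": 1, "L": 1, "S": 1}

WATER_MASS = 18.0153
_MEAN_RESIDUE_WEIGHT = sum(protein_weights.values()) / len(protein_weights)


class AnchoringError(ValueError):
    """Fewer than two NPA-motif candidates, or no admissible candidate pair."""


@dataclass(frozen=True)
class TmSegmentation:
    """Predicted transmembrane segments as 0-based half-open residue intervals."""

    segments: tuple[tuple[int, int], ...]
    window: int
    threshold: float

    def __post_init__(self) -> None:
        prev = None
        for start, end in self.segments:
            if end - start < 12:
                raise ValueError(f"segment ({start},{end}) shorter than 12 residues")
            if prev is not None and start < prev:
                raise ValueError("segments unsorted or overlapping")
            prev = end

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class NpaAnchor:
    """One anchored NPA motif: loop (B or E), index of the Asn, tripeptide."""

    loop: str
    n_index: int
    tripeptide: str

    def __post_init__(self) -> None:
        if self.loop not in {"B", "E"}:
            raise ValueError("loop must be 'B' or 'E'")
        if self.tripeptide[0] != "N" or self.tripeptide[1] != "P":
            raise ValueError(f"not an N-P-x tripeptide: {self.tripeptide!r}")
        if self.tripeptide[2] not in NPA_THIRD_RESIDUES:
            raise ValueError(f"third residue {self.tripeptide[2]!r} not tolerated")


@dataclass(frozen=True)
class ScreenVerdict:
    """Completeness verdict for one record; complete iff no rule failed."""

    record_id: str
    status: str
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.status == "complete") != (not self.reasons):
            raise ValueError("status 'complete' requires empty reasons and vice versa")


@dataclass(frozen=True)
class MwResult:
    """Molecular weight in kDa; approximate when undetermined residues present."""

    kda: float
    approximate: bool = False

    def __float__(self) -> float:
        return self.kda


def predict_tm_segments(
    record: ProteinRecord, window: int = 19, threshold: float = 1.6
) -> TmSegmentation:
    """Segment a sequence into putative TM helices by window-mean hydropathy.

    A residue belongs to a raw segment when the mean Kyte-Doolittle hydropathy
    of the ``window`` residues centered on it is at least ``threshold``. Raw
    runs separated by fewer than 3 residues are merged, and runs shorter than
    12 residues are discarded.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    seq = record.sequence
    if len(seq) < window:
        raise ValueError(
            f"{record.id}: sequence length {len(seq)} shorter than window {window}"
        )
    half = window // 2
    values = [KYTE_DOOLITTLE[aa] for aa in seq]
    # rolling window means for centers half .. len-half-1
    acc = sum(values[:window])
    means = [acc / window]
    for i in range(window, len(values)):
        acc += values[i] - values[i - window]
        means.append(acc / window)
    # raw runs of qualifying centers, in residue coordinates
    runs: list[list[int]] = []
    for center_offset, mean in enumerate(means):
        pos = center_offset + half
        if mean >= threshold:
            if runs and runs[-1][1] == pos:
                runs[-1][1] = pos + 1
            else:
                runs.append([pos, pos + 1])
    # merge runs separated by < 3 residues, then drop short ones
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] < 3:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    segments = tuple((s, e) for s, e in merged if e - s >= 12)
    return TmSegmentation(segments=segments, window=window, threshold=threshold)


def _npa_candidates(seq: str, tolerated: frozenset[str]) -> list[int]:
    return [
        i
        for i in range(len(seq) - 2)
        if seq[i] == "N" and seq[i + 1] == "P" and seq[i + 2] in tolerated
    ]


def _best(seq: str, candidates: Sequence[int]) -> int:
    return max(candidates, key=lambda i: (_THIRD_SCORE.get(seq[i + 2], 0), -i))


def find_npa_anchors(
    record: ProteinRecord,
    tm: TmSegmentation | None = None,
    tolerated: frozenset[str] = NPA_THIRD_RESIDUES,
    min_separation: int = 80,
    max_separation: int = 160,
) -> tuple[NpaAnchor, NpaAnchor]:
    """Locate the loop-B and loop-E NPA motifs.

    Scans for N-P-x tripeptides with x in the tolerated set. With a six-helix
    segmentation, the loop-B motif is sought between TM2 and TM3 and the
    loop-E motif between TM5 and TM6. Otherwise (or when a loop holds no
    candidate) the fallback selects the candidate pair separated by
    ``min_separation``-``max_separation`` residues whose third residues score
    highest under the preference A > T,V,L,S > others.
    """
    seq = record.sequence
    candidates = _npa_candidates(seq, tolerated)
    if len(candidates) < 2:
        raise AnchoringError(
            f"{record.id}: found {len(candidates)} N-P-x candidate(s), need 2"
        )
    if tm is not None and len(tm) == 6:
        segs = tm.segments
        loop_b = [i for i in candidates if segs[1][1] <= i < segs[2][0]]
        loop_e = [i for i in candidates if segs[4][1] <= i < segs[5][0]]
        if loop_b and loop_e:
            b = _best(seq, loop_b)
            e = _best(seq, loop_e)
            return (
                NpaAnchor("B", b, seq[b : b + 3]),
                NpaAnchor("E", e, seq[e : e + 3]),
            )
    best_pair: tuple[int, int] | None = None
    best_score = -1
    for i in candidates:
        for j in candidates:
            if j <= i or not (min_separation <= j - i <= max_separation):
                continue
            score = _THIRD_SCORE.get(seq[i + 2], 0) + _THIRD_SCORE.get(seq[j + 2], 0)
            if score > best_score:
                best_score, best_pair = score, (i, j)
    if best_pair is None:
        raise AnchoringError(
            f"{record.id}: no candidate pair separated by "
            f"{min_separation}-{max_separation} residues"
        )
    b, e = best_pair
    return (NpaAnchor("B", b, seq[b : b + 3]), NpaAnchor("E", e, seq[e : e + 3]))


def screen_record(
    record: ProteinRecord,
    tm: TmSegmentation,
    anchors: tuple[NpaAnchor, NpaAnchor] | None,
    min_length: int = 200,
    max_length: int = 400,
    min_tm: int = 5,
) -> ScreenVerdict:
    """Completeness screen codifying the manual pseudogene inspection.

    A record is complete when its length is plausible for a full-length MIP
    (200-400 residues by default), at least ``min_tm`` TM segments are found,
    and both NPA anchors resolved. Failures are verdicts, not errors.
    """
    reasons: list[str] = []
    if not (min_length <= len(record) <= max_length):
        reasons.append("length")
    if len(tm) < min_tm:
        reasons.append("tm_count")
    if anchors is None:
        reasons.append("npa_anchors")
    status = "complete" if not reasons else "pseudogene_like"
    return ScreenVerdict(record_id=record.id, status=status, reasons=tuple(reasons))


def compute_mw(record: ProteinRecord) -> MwResult:
    """Average-mass molecular weight in kDa (residue masses + one water).

    Undetermined residues (X) are scored with the mean residue mass and the
    result flagged approximate.
    """
    total = 0.0
    approximate = False
    for aa in record.sequence:
        if aa == "X":
            total += _MEAN_RESIDUE_WEIGHT - WATER_MASS
            approximate = True
        else:
            total += protein_weights[aa] - WATER_MASS
    total += WATER_MASS
    return MwResult(kda=total / 1000.0, approximate=approximate)


def compute_pi(record: ProteinRecord, tolerance: float = 0.01) -> float:
    """Isoelectric point by bisection of the Bjellqvist net-charge curve.

    Uses the Bjellqvist pKa table (via Biopython's charge function) and
    bisects on pH in [0, 14] until the bracket is narrower than ``tolerance``.
    """
    ip = IsoelectricPoint(record.sequence.replace("X", ""))
    lo, hi = 0.0, 14.0
    while hi - lo > tolerance:
        mid = (lo + hi) / 2.0
        if ip.charge_at_pH(mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
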