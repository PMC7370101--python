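"""Deterministic generators of MIP-like test worlds.

Every generator is a pure function of its spec and an integer seed, and
returns a ground-truth manifest alongside the data so each pipeline stage
has a recoverable answer:

* subfamily-group reference templates with planted NPA motifs, ar/R filter,
  Froger positions and NPA-region strings, laid out as six strongly
  hydrophobic blocks separated by polar loops;
* mutated families at a chosen per-residue divergence (substitutions only,
  never at protected signature positions, and never creating a new Asn-Pro
  dipeptide that could confuse motif anchoring);
* exon/intron gene models;
* FPKM matrices with a known expressed/not-expressed partition in which
  replicate noise is mean-preserving, so the planted labels are exactly
  recoverable under the strict FPKM > 1 calling rule.

The emulated world is deliberately simple: no indel process, no rate
heterogeneity, and template backbones that are more regular than real
membrane proteins.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from aqpkit.io_formats import GeneModel, ProteinRecord, ExpressionMatrix
from aqpkit.subfamily_classification import ReferenceTemplate

__all__ = [
    "FamilySpec",
    "GroundTruthManifest",
    "RecordTruth",
    "SIGNATURE_SPECS",
    "CANONICAL_GROUPS",
    "build_template",
    "build_reference_set",
    "simulate_family",
    "simulate_gene_models",
    "simulate_fpkm",
]

# ---------------------------------------------------------------------------
# Planted signature strings per subfamily-group.
#
# Within each dict: arR = (H2, H5, LE1, LE2); lb = 10-mer around the loop-B
# NPA (Asn at offset 5); le = 11-mer around the loop-E NPA (Asn at offset 4,
# LE1 at offset 1, LE2 at offset 7); fp = P1..P5. The strings are mutually
# consistent (le[1] == arR[2], le[7] == arR[3]) and chosen as fixed
# representatives of the published pattern classes: canonical PIPs carry the
# CO2 exemplars, NIP2 the silicon exemplars, NIP5 a boron-class signature
# with the loop-E NPV variant, SIPs the loop-B NPT/NPL variants, and XIPs
# the loop-B NPV variant.

SIGNATURE_SPECS: dict[tuple[str, int], dict[str, str]] = {
    ("PIP", 1): dict(arR="FHTR", lb="SGGHINPAVT", le="GTGINPARSLG", fp="MSAFW"),
    ("PIP", 2): dict(arR="FHTR", lb="SGGHINPAVT", le="GTGINPARSLG", fp="QSAFW"),
    ("TIP", 1): dict(arR="HIAV", lb="SGAHINPAVT", le="GASMNPAVSLG", fp="TSAYW"),
    ("TIP", 2): dict(arR="HIGR", lb="SGGHLNPAVT", le="GGSMNPARSLG", fp="TSAYW"),
    ("TIP", 4): dict(arR="HIAR", lb="SGGHVNPAVT", le="GASMNPARSFG", fp="TSAYW"),
    ("NIP", 1): dict(arR="WVAR", lb="SGAHLNPAVT", le="GASMNPARSLG", fp="FTAYF"),
    ("NIP", 2): dict(arR="GSGR", lb="SGAHMNPAVT", le="GGSMNPARTLG", fp="LTAYF"),
    ("NIP", 5): dict(arR="AIGR", lb="SGAHLNPAVT", le="GGSMNPVRSLG", fp="FTAYL"),
    ("SIP", 1): dict(arR="IVPF", lb="SGGHINPTVT", le="GPSINPAFSKG", fp="ASAFW"),
    ("SIP", 2): dict(arR="IVPN", lb="SGGHINPLVT", le="GPSINPANSKG", fp="ASAFW"),
    ("XIP", 1): dict(arR="IVAR", lb="SGGHINPVVT", le="GASMNPARSLG", fp="VCAYW"),
    ("XIP", 2): dict(arR="VVAR", lb="SGGHINPVVT", le="GASMNPARSLG", fp="VCAYW"),
}

#: Group used when a single template per subfamily is wanted.
CANONICAL_GROUPS = {"PIP": 1, "TIP": 2, "NIP": 2, "SIP": 1, "XIP": 1}

# Hydrophobic block alphabet (strong Kyte-Doolittle values) and the polar
# loop/tail alphabet; the mildly polar loop mix keeps window means below the
# segmentation threshold while letting detected segments end close to the
# planted block boundaries.
_TM_ALPHABET = "ILV"
_LOOP_ALPHABET = "GSTGSTPN"
_POLAR_STRONG = "DEKN"

_TM_LEN = 21
_LAYOUT = dict(
    nterm=24, tm1=_TM_LEN, loop_a=14, tm2=_TM_LEN, tm3=_TM_LEN, loop_c=30,
    tm4=_TM_LEN, loop_d=12, tm5=_TM_LEN, tm6=_TM_LEN, cterm=28,
)
_H2_OFFSET_IN_TM2 = 16
_H5_OFFSET_IN_TM5 = 10


def _rng_for(label: str) -> np.random.Generator:
    """Deterministic, platform-stable RNG keyed by a string label."""
    return np.random.default_rng(zlib.crc32(label.encode()))


def _draw(rng: np.random.Generator, alphabet: str, n: int) -> list[str]:
    return [alphabet[k] for k in rng.integers(0, len(alphabet), n)]


@dataclass(frozen=True)
class FamilySpec:
    """Counts per subfamily-group, divergence and seed for a simulated family."""

    counts: Mapping[tuple[str, int], int]
    divergence: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError("divergence must be in [0, 0.5]")
        for key, n in self.counts.items():
            if key not in SIGNATURE_SPECS:
                raise ValueError(f"no template defined for subfamily-group {key}")
            if n < 0:
                raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class RecordTruth:
    """Planted ground truth for one simulated protein."""

    subfamily: str
    group: int
    template_id: str
    arR: str
    froger: str
    lb_region: str
    le_region: str
    coords: Mapping[str, int]
    tm_intervals: tuple[tuple[int, int], ...]
    raw_substrates: frozenset[str]


@dataclass
class GroundTruthManifest:
    """Ground truth for every generated entity of one synthetic world."""

    records: dict[str, RecordTruth] = field(default_factory=dict)
    gene_structures: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)
    expressed: dict[tuple[str, str], bool] = field(default_factory=dict)


def _build_backbone(subfamily: str, group: int) -> tuple[str, dict[str, int], tuple[tuple[int, int], ...]]:
    """Assemble the template sequence, annotated positions and TM intervals."""
    sig = SIGNATURE_SPECS[(subfamily, group)]
    rng = _rng_for(f"backbone:{subfamily}")
    parts: list[str] = []
    tm_intervals: list[tuple[int, int]] = []
    pos = 0

    def emit(chars: Sequence[str]) -> None:
        nonlocal pos
        parts.append("".join(chars))
        pos += len(chars)

    def emit_tm() -> tuple[int, int]:
        start = pos
        emit(_draw(rng, _TM_ALPHABET, _TM_LEN))
        tm_intervals.append((start, pos))
        return start, pos

    coords: dict[str, int] = {}

    emit(_draw(rng, _LOOP_ALPHABET, _LAYOUT["nterm"]))
    emit_tm()                                            # TM1
    emit(_draw(rng, _LOOP_ALPHABET, _LAYOUT["loop_a"]))
    tm2_start, _ = emit_tm()                             # TM2 (H2 planted later)
    coords["H2"] = tm2_start + _H2_OFFSET_IN_TM2
    # loop B: strongly polar flanks around the planted 10-mer
    emit(_draw(rng, _POLAR_STRONG, 3))
    coords["NPA1_N"] = pos + 5
    emit(sig["lb"])
    emit(_draw(rng, _POLAR_STRONG, 6))
    emit_tm()                                            # TM3
    emit(_draw(rng, _LOOP_ALPHABET, _LAYOUT["loop_c"]))
    emit_tm()                                            # TM4
    emit(_draw(rng, _LOOP_ALPHABET, _LAYOUT["loop_d"]))
    tm5_start, _ = emit_tm()                             # TM5 (H5 planted later)
    coords["H5"] = tm5_start + _H5_OFFSET_IN_TM5
    # loop E: planted 11-mer, then P1, inside polar flanks
    emit(_draw(rng, _POLAR_STRONG, 2))
    coords["NPA2_N"] = pos + 4
    coords["LE1"] = pos + 1
    coords["LE2"] = pos + 7
    emit(sig["le"])
    emit(_draw(rng, _POLAR_STRONG, 3))
    coords["P1"] = pos
    emit("A")  # placeholder, overwritten by the FP plant below
    emit(_draw(rng, _POLAR_STRONG, 4))
    emit_tm()                                            # TM6
    # C-terminal tail carrying P2..P5
    tail = _draw(rng, _LOOP_ALPHABET, _LAYOUT["cterm"])
    for k, offset in enumerate((3, 8, 13, 18), start=2):
        coords[f"P{k}"] = pos + offset
    emit(tail)

    seq = list("".join(parts))
    seq[coords["H2"]] = sig["arR"][0]
    seq[coords["H5"]] = sig["arR"][1]
    for k, res in enumerate(sig["fp"], start=1):
        seq[coords[f"P{k}"]] = res
    return "".join(seq), coords, tuple(tm_intervals)


def _strip_stray_npa(seq: list[str], protected: set[int]) -> None:
    """Remove chance Asn-Pro dipeptides outside the protected windows."""
    for i in range(len(seq) - 1):
        if seq[i] == "N" and seq[i + 1] == "P":
            if i in protected and i + 1 in protected:
                continue
            target = i + 1 if (i + 1) not in protected else i
            replacement = "S" if seq[target] != "S" else "T"
            seq[target] = replacement


def _group_differentiation(
    seq: list[str], subfamily: str, group: int, mutable: list[int],
    rng_label: str, rate: float = 0.12,
) -> None:
    rng = _rng_for(rng_label)
    for i in mutable:
        if rng.random() < rate:
            choices = [c for c in _LOOP_ALPHABET if c != seq[i]]
            seq[i] = choices[rng.integers(0, len(choices))]


def _protected_positions(coords: Mapping[str, int]) -> set[int]:
    protected = set(coords.values())
    protected |= set(range(coords["NPA1_N"] - 5, coords["NPA1_N"] + 5))
    protected |= set(range(coords["NPA2_N"] - 4, coords["NPA2_N"] + 7))
    return protected


def build_template(subfamily: str, group: int | None = None) -> ReferenceTemplate:
    """Deterministic annotated reference template for one subfamily-group.

    The template has six hydrophobic blocks of 21 residues separated by polar
    loops; loop B and loop E embed the subfamily's planted NPA-region strings,
    and the ar/R and Froger residues sit at the recorded annotation indices.
    """
    if group is None:
        group = CANONICAL_GROUPS[subfamily]
    if (subfamily, group) not in SIGNATURE_SPECS:
        raise ValueError(f"no template defined for {subfamily} group {group}")
    seq_str, coords, tm = _build_backbone(subfamily, group)
    seq = list(seq_str)
    protected = _protected_positions(coords)
    # group-specific drift confined to unprotected loop/tail residues
    in_tm = set()
    for start, end in tm:
        in_tm |= set(range(start, end))
    mutable = [
        i for i in range(len(seq))
        if i not in protected and i not in in_tm
    ]
    _group_differentiation(seq, subfamily, group, mutable, f"group:{subfamily}:{group}")
    _strip_stray_npa(seq, protected)
    return ReferenceTemplate(
        id=f"{subfamily}{group}_template",
        subfamily=subfamily,
        group=group,
        sequence="".join(seq),
        positions=coords,
    )


def build_reference_set(keys: Sequence[tuple[str, int]] | None = None) -> list[ReferenceTemplate]:
    """The packaged annotated reference set (one template per subfamily-group)."""
    if keys is None:
        keys = sorted(SIGNATURE_SPECS)
    return [build_template(s, g) for s, g in keys]


def _template_truth(template: ReferenceTemplate) -> RecordTruth:
    from aqpkit.io_formats import load_sdp_table
    from aqpkit.substrate_prediction import match_component

    sig = SIGNATURE_SPECS[(template.subfamily, template.group)]
    raw = set()
    for row in load_sdp_table():
        strings = {"arR": sig["arR"], "lb": sig["lb"], "le": sig["le"], "fp": sig["fp"]}
        if all(
            match_component(strings[name], classes)[0]
            for name, classes in row.components.items()
        ):
            raw.add(row.substrate)
    seq = template.sequence
    n1, n2 = template.positions["NPA1_N"], template.positions["NPA2_N"]
    tm = tuple(
        iv for iv in _build_backbone(template.subfamily, template.group)[2]
    )
    return RecordTruth(
        subfamily=template.subfamily,
        group=template.group,
        template_id=template.id,
        arR=sig["arR"],
        froger=sig["fp"],
        lb_region=seq[n1 - 5 : n1 + 5],
        le_region=seq[n2 - 4 : n2 + 7],
        coords=dict(template.positions),
        tm_intervals=tm,
        raw_substrates=frozenset(raw),
    )


def simulate_family(spec: FamilySpec) -> tuple[list[ProteinRecord], GroundTruthManifest]:
    """Simulate a family: each record is its group template with i.i.d.
    substitutions at unprotected positions at the spec's divergence.

    Substitutions are drawn uniformly over the other 19 residues but re-drawn
    whenever they would create a new Asn-Pro dipeptide, so the two planted
    NPA motifs stay the only anchor candidates. Regeneration with the same
    spec is byte-identical.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    records: list[ProteinRecord] = []
    manifest = GroundTruthManifest()
    for (subfamily, group) in sorted(spec.counts):
        n = spec.counts[(subfamily, group)]
        template = build_template(subfamily, group)
        truth = _template_truth(template)
        protected = _protected_positions(template.positions)
        for k in range(n):
            seq = list(template.sequence)
            for i in range(len(seq)):
                if i in protected or rng.random() >= spec.divergence:
                    continue
                while True:
                    cand = alphabet[rng.integers(0, 20)]
                    if cand == template.sequence[i]:
                        continue
                    if cand == "P" and i > 0 and seq[i - 1] == "N":
                        continue
                    if cand == "N" and i + 1 < len(seq) and seq[i + 1] == "P":
                        continue
                    break
                seq[i] = cand
            rid = f"syn_{subfamily}{group}_{k:03d}"
            records.append(ProteinRecord(id=rid, sequence="".join(seq)))
            manifest.records[rid] = truth
    return records, manifest


def simulate_gene_models(
    intron_count_spec: Mapping[str, int] | Sequence[tuple[str, int]],
    seed: int = 0,
    long_intron_genes: Sequence[str] = (),
) -> tuple[list[GeneModel], GroundTruthManifest]:
    """Simulate gene models with given intron counts per gene.

    Exon lengths are drawn uniformly in 50-300 bp and intron lengths in
    80-2000 bp; genes named in ``long_intron_genes`` get one planted intron
    of at least 10 kb. Deterministic under the seed.
    """
    items = list(intron_count_spec.items()) if isinstance(intron_count_spec, Mapping) \
        else list(intron_count_spec)
    rng = np.random.default_rng(seed)
    models: list[GeneModel] = []
    manifest = GroundTruthManifest()
    for gene_id, n_introns in items:
        if n_introns < 0:
            raise ValueError(f"{gene_id}: intron count must be >= 0")
        n_exons = n_introns + 1
        exon_lengths = rng.integers(50, 301, n_exons)
        intron_lengths = rng.integers(80, 2001, n_introns)
        if gene_id in set(long_intron_genes) and n_introns > 0:
            intron_lengths[int(rng.integers(0, n_introns))] = int(rng.integers(10_000, 15_001))
        exons = []
        cursor = 0
        for i in range(n_exons):
            exons.append((cursor, cursor + int(exon_lengths[i])))
            cursor = exons[-1][1]
            if i < n_introns:
                cursor += int(intron_lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        model = GeneModel(gene_id=gene_id, strand=strand, exons=tuple(exons))
        models.append(model)
        manifest.gene_structures[gene_id] = tuple(exons)
    return models, manifest


def simulate_fpkm(
    n_genes: int,
    conditions: Sequence[str],
    replicates: int = 3,
    expressed_fraction: float = 0.8,
    seed: int = 0,
    expressed_counts: Mapping[str, int] | None = None,
) -> tuple[ExpressionMatrix, GroundTruthManifest]:
    """Simulate an FPKM matrix with a known expressed/not-expressed partition.

    Expressed (gene, condition) cells draw log10 mean FPKM from N(1.0, 0.5)
    floored at FPKM 1.25; non-expressed cells draw uniform [0, 0.8].
    Replicate noise is multiplicative log-normal (sd 0.1) renormalized to
    preserve the replicate mean, so the planted label always agrees with the
    strict mean-FPKM > 1 calling rule. ``expressed_counts`` plants an exact
    number of expressed genes per condition, overriding the fraction.
    """
    import pandas as pd

    if not 0.0 <= expressed_fraction <= 1.0:
        raise ValueError("expressed_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"gene{k:03d}" for k in range(n_genes)]
    manifest = GroundTruthManifest()
    columns: dict[str, np.ndarray] = {}
    design: dict[str, tuple[str, int]] = {}
    for cond in conditions:
        if expressed_counts is not None:
            count = expressed_counts[cond]
            if not 0 <= count <= n_genes:
                raise ValueError(f"{cond}: planted count {count} out of range")
            chosen = rng.permutation(n_genes)[:count]
            labels = np.zeros(n_genes, dtype=bool)
            labels[chosen] = True
        else:
            labels = rng.random(n_genes) < expressed_fraction
        base = np.where(
            labels,
            np.maximum(10.0 ** rng.normal(1.0, 0.5, n_genes), 1.25),
            rng.uniform(0.0, 0.8, n_genes),
        )
        noise = np.exp(rng.normal(0.0, 0.1 * np.log(10), (n_genes, replicates)))
        noise /= noise.mean(axis=1, keepdims=True)  # mean-preserving
        for r in range(replicates):
            sample = f"{cond}_rep{r + 1}"
            columns[sample] = base * noise[:, r]
            design[sample] = (cond, r + 1)
        for g, lab in zip(genes, labels):
            manifest.expressed[(g, cond)] = bool(lab)
    values = pd.DataFrame(columns, index=genes)
    return ExpressionMatrix(values, design), manifest
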