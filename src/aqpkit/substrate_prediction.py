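"""Substrate prediction from selectivity signatures.

Each candidate substrate (boron, CO2, H2O2, ammonia, silicon, urea, arsenic,
antimony) is described by four position-wise residue-class patterns over the
ar/R filter (4 positions), the loop-B NPA region (10), the loop-E NPA region
(11) and the Froger positions (5). A protein is a raw match for a substrate
when every component of its signature satisfies the corresponding pattern.

Raw pattern matching over-calls: several substrate rows share residue
classes, so a signature satisfying the silicon row typically also satisfies
the arsenic/antimony/urea classes. The ``restricted`` mode therefore applies
subfamily gates (shipped as a data file, user-overridable) that reproduce
the published per-substrate transporter rosters, which embed subfamily
priors from the experimental literature.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SdpPattern",
    "SubstrateCalls",
    "PatternSyntaxError",
    "compile_pattern",
    "match_component",
    "predict_substrates",
    "expand_roster",
    "roster_summary",
    "load_gates",
]

_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

COMPONENT_LENGTHS = {"arR": 4, "lb": 10, "le": 11, "fp": 5}


class PatternSyntaxError(ValueError):
    """Malformed residue-class pattern string."""


@dataclass(frozen=True)
class SdpPattern:
    """One substrate row: four fixed-length position-wise residue-class patterns."""

    substrate: str
    arR_classes: tuple[frozenset[str], ...]
    lb_classes: tuple[frozenset[str], ...]
    le_classes: tuple[frozenset[str], ...]
    fp_classes: tuple[frozenset[str], ...]
    printed_roster: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name, classes in self.components.items():
            want = COMPONENT_LENGTHS[name]
            if len(classes) != want:
                raise ValueError(
                    f"{self.substrate}: {name} pattern has {len(classes)} "
                    f"positions, expected {want}"
                )
            for i, cls in enumerate(classes):
                if not cls or not set(cls) <= _ALPHABET:
                    raise ValueError(
                        f"{self.substrate}: invalid residue class at {name}[{i}]"
                    )

    @property
    def components(self) -> dict[str, tuple[frozenset[str], ...]]:
        return {
            "arR": self.arR_classes,
            "lb": self.lb_classes,
            "le": self.le_classes,
            "fp": self.fp_classes,
        }


@dataclass(frozen=True)
class SubstrateCalls:
    """Predicted substrates for one record.

    ``raw_matches`` are substrates whose four patterns all match;
    ``restricted_matches`` is the subset surviving the subfamily gates.
    ``detail`` maps substrate -> component name -> (ok, first failing index).
    """

    record_id: str
    raw_matches: frozenset[str]
    restricted_matches: frozenset[str]
    detail: Mapping[str, Mapping[str, tuple[bool, int | None]]]
    reason: str | None = None

    def __post_init__(self) -> None:
        if not self.restricted_matches <= self.raw_matches:
            raise ValueError("restricted matches must be a subset of raw matches")


def compile_pattern(pattern: str) -> tuple[frozenset[str], ...]:
    """Compile a pattern string like ``"[AGI][ISV][GA]R"`` to residue-class sets.

    A bare uppercase letter is a singleton class; ``[...]`` groups are the set
    of their letters. Unbalanced brackets, empty groups and characters outside
    the 20-letter alphabet are syntax errors.
    """
    classes: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.find("]", i)
            if j == -1:
                raise PatternSyntaxError(f"unclosed '[' at position {i}: {pattern!r}")
            group = pattern[i + 1 : j]
            if not group:
                raise PatternSyntaxError(f"empty class group at position {i}: {pattern!r}")
            if not set(group) <= _ALPHABET:
                raise PatternSyntaxError(f"invalid residues in group {group!r}")
            classes.append(frozenset(group))
            i = j + 1
        elif ch in _ALPHABET:
            classes.append(frozenset(ch))
            i += 1
        else:
            raise PatternSyntaxError(f"unexpected character {ch!r} in {pattern!r}")
    if not classes:
        raise PatternSyntaxError("empty pattern")
    return tuple(classes)


def match_component(
    residues: str, classes: Sequence[frozenset[str]]
) -> tuple[bool, int | None]:
    """Positionwise class match: true iff ``residues[i]`` is in ``classes[i]``
    for all i. Returns ``(ok, first_failing_index)``."""
    if len(residues) != len(classes):
        raise ValueError(
            f"residue string length {len(residues)} != pattern length {len(classes)}"
        )
    for i, (res, cls) in enumerate(zip(residues, classes)):
        if res not in cls:
            return False, i
    return True, None


# ---------------------------------------------------------------------------
# Subfamily gates for restricted mode

_DEFAULT_GATES_FILE = "substrate_gates.json"


def load_gates(path: str | None = None) -> dict[str, list[dict]]:
    """Load restricted-mode subfamily gates.

    Each substrate maps to a list of clauses; a record passes if any clause
    matches. Clause keys: ``subfamily`` (required), ``group`` (optional int),
    ``arR`` (optional exact ar/R string). A substrate absent from the file is
    ungated.
    """
    if path is None:
        text = resources.files("aqpkit.data").joinpath(_DEFAULT_GATES_FILE).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return json.loads(text)


def _gate_passes(
    clauses: list[dict], subfamily: str | None, group: int | None, arR: str
) -> bool:
    for clause in clauses:
        if subfamily != clause.get("subfamily"):
            continue
        if "group" in clause and group != clause["group"]:
            continue
        if "arR" in clause and arR != clause["arR"]:
            continue
        return True
    return False


def predict_substrates(
    sig,
    table: Iterable[SdpPattern],
    mode: str = "raw",
    subfamily: str | None = None,
    group: int | None = None,
    gates: Mapping[str, list[dict]] | None = None,
) -> SubstrateCalls:
    """Match one signature against every substrate row.

    Parameters
    ----------
    sig : SignatureSet
        Extracted signature; a flagged signature yields empty calls with a
        reason rather than an error.
    mode : {"raw", "restricted"}
        ``restricted`` additionally applies the subfamily gates, for which
        ``subfamily`` (and where gated, ``group``) of the record must be given.
    """
    if mode not in {"raw", "restricted"}:
        raise ValueError(f"unknown mode {mode!r} (expected 'raw' or 'restricted')")
    if sig.flags:
        return SubstrateCalls(
            record_id=sig.record_id,
            raw_matches=frozenset(),
            restricted_matches=frozenset(),
            detail={},
            reason="signature has unresolved positions: " + ", ".join(sorted(sig.flags)),
        )
    if gates is None:
        gates = load_gates()
    strings = {"arR": sig.arR, "lb": sig.lb_region, "le": sig.le_region, "fp": sig.froger}
    detail: dict[str, dict[str, tuple[bool, int | None]]] = {}
    raw: set[str] = set()
    restricted: set[str] = set()
    for row in table:
        comp_detail = {
            name: match_component(strings[name], classes)
            for name, classes in row.components.items()
        }
        detail[row.substrate] = comp_detail
        if all(ok for ok, _ in comp_detail.values()):
            raw.add(row.substrate)
            clauses = gates.get(row.substrate)
            if mode == "raw" or clauses is None or _gate_passes(
                clauses, subfamily, group, sig.arR
            ):
                restricted.add(row.substrate)
    if mode == "raw":
        restricted = set(raw)
    return SubstrateCalls(
        record_id=sig.record_id,
        raw_matches=frozenset(raw),
        restricted_matches=frozenset(restricted),
        detail=detail,
    )


# ---------------------------------------------------------------------------
# Printed rosters

_ROSTER_TOKEN_RE = re.compile(
    r"^(?P<stem>\S*?(?:PIP|TIP|NIP|SIP|XIP)\d+;)(?P<i>\d+)(?:[–-](?P<j>\d+))?$"
)


def expand_roster(roster: str | Sequence[str]) -> list[str]:
    """Expand roster range notation to individual isoform names.

    ``"NtPIP1;4–8"`` (en-dash or hyphen) expands inclusively to
    ``NtPIP1;4 ... NtPIP1;8``; single tokens pass through. Input order is
    preserved.
    """
    if isinstance(roster, str):
        tokens = [tok.strip() for tok in roster.split(",") if tok.strip()]
    else:
        tokens = [tok.strip() for tok in roster]
    names: list[str] = []
    for token in tokens:
        m = _ROSTER_TOKEN_RE.match(token)
        if m is None:
            raise ValueError(f"unparseable roster token {token!r}")
        lo = int(m.group("i"))
        hi = int(m.group("j")) if m.group("j") else lo
        if hi < lo:
            raise ValueError(f"inverted range in roster token {token!r}")
        names.extend(f"{m.group('stem')}{k}" for k in range(lo, hi + 1))
    return names


_SUBFAMILY_RE = re.compile(r"(PIP|TIP|NIP|SIP|XIP)")


def roster_summary(table: Iterable[SdpPattern]) -> dict[str, dict]:
    """Expand every substrate's printed roster and count names per subfamily."""
    summary: dict[str, dict] = {}
    for row in table:
        names = expand_roster(list(row.printed_roster))
        per_subfamily: dict[str, int] = {}
        for name in names:
            m = _SUBFAMILY_RE.search(name)
            key = m.group(1) if m else "?"
            per_subfamily[key] = per_subfamily.get(key, 0) + 1
        summary[row.substrate] = {
            "names": names,
            "total": len(names),
            "by_subfamily": per_subfamily,
        }
    return summary
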