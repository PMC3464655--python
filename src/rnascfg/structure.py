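"""Secondary structures, dot-bracket text, Vienna-style records, and dataset filtering.

A secondary structure is a set of base pairs ``(i, j)`` with ``i < j`` over
0-based sequence positions, each position in at most one pair.  The external
representation is dot-bracket text: ``.`` for an unpaired position, ``(`` for a
position paired with the corresponding ``)``.  This single-bracket alphabet can
only express non-crossing (pseudoknot-free) structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Structure",
    "StructuredSequence",
    "parse_dotbracket",
    "to_dotbracket",
    "detect_pseudoknot",
    "min_hairpin_length",
    "base_pair_similarity",
    "read_records",
    "write_records",
    "parse_records",
    "format_records",
    "filter_dataset",
]

RNA_ALPHABET = "ACGU"


class StructureError(ValueError):
    """Malformed structure text or inconsistent record."""


@dataclass(frozen=True)
class Structure:
    """A pseudoknot-free secondary structure as a set of 0-based pairs."""

    length: int
    pairs: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise StructureError(f"pair ({i},{j}) outside [0,{self.length})")
            if i in seen or j in seen:
                raise StructureError(f"position reused in pair ({i},{j})")
            seen.add(i)
            seen.add(j)

    @property
    def paired_positions(self) -> frozenset[int]:
        return frozenset(p for ij in self.pairs for p in ij)

    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    def __str__(self) -> str:
        return to_dotbracket(self)


@dataclass(frozen=True)
class StructuredSequence:
    """An RNA sequence with a trusted secondary structure of equal length."""

    id: str
    sequence: str
    structure: Structure

    def __post_init__(self) -> None:
        if len(self.sequence) != self.structure.length:
            raise StructureError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"structure length {self.structure.length}"
            )


def parse_dotbracket(text: str) -> Structure:
    """Parse dot-bracket text into a :class:`Structure` (stack matching)."""
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(text):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return Structure(length=len(text), pairs=frozenset(pairs))


def to_dotbracket(structure: Structure) -> str:
    chars = ["."] * structure.length
    for i, j in structure.pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def detect_pseudoknot(pairs: Iterable[tuple[int, int]]) -> bool:
    """True iff two pairs cross: (i,j), (k,l) with i < k < j < l."""
    plist = sorted(pairs)
    seen: set[int] = set()
    for i, j in plist:
        if i in seen or j in seen:
            raise StructureError(f"position reused in pair ({i},{j})")
        seen.add(i)
        seen.add(j)
    for a in range(len(plist)):
        i, j = plist[a]
        for b in range(a + 1, len(plist)):
            k, l = plist[b]
            if k >= j:
                break
            if i < k < j < l:
                return True
    return False


def min_hairpin_length(structure: Structure) -> float:
    """Minimum unpaired span ``j - i - 1`` over hairpin-closing pairs.

    A hairpin-closing pair is one that encloses no other pair.  Returns
    ``math.inf`` when the structure has no pairs.
    """
    if not structure.pairs:
        return math.inf
    spans = sorted(structure.pairs)
    best = math.inf
    for idx, (i, j) in enumerate(spans):
        encloses = False
        for k, l in spans[idx + 1 :]:
            if k >= j:
                break
            if i < k and l < j:
                encloses = True
                break
        if not encloses:
            best = min(best, j - i - 1)
    return best


def base_pair_similarity(a: Structure, b: Structure) -> float:
    """Fraction of shared pairs, |shared| / max(|pairs_a|, |pairs_b|).

    Defined as 0 for structures of unequal length or when either structure
    has no pairs (conservative, symmetric, parameter-free).
    """
    if a.length != b.length or not a.pairs or not b.pairs:
        return 0.0
    return len(a.pairs & b.pairs) / max(len(a.pairs), len(b.pairs))


def _normalise_sequence(seq: str, rec_id: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set(RNA_ALPHABET)
    if bad:
        raise StructureError(
            f"record {rec_id!r}: invalid sequence characters {sorted(bad)} "
            "(ambiguity codes are rejected)"
        )
    return seq


def parse_records(text: str) -> list[StructuredSequence]:
    """Parse Vienna-style records: ``>id`` line, sequence line, structure line."""
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    records: list[StructuredSequence] = []
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StructureError(f"expected '>' header, got {lines[i]!r}")
        rec_id = lines[i][1:].strip()
        if i + 2 >= len(lines):
            raise StructureError(f"record {rec_id!r}: truncated record")
        seq = _normalise_sequence(lines[i + 1].strip(), rec_id)
        struct_text = lines[i + 2].strip()
        try:
            structure = parse_dotbracket(struct_text)
        except StructureError as exc:
            raise StructureError(f"record {rec_id!r}: {exc}") from exc
        if len(seq) != structure.length:
            raise StructureError(
                f"record {rec_id!r}: sequence/structure length mismatch "
                f"({len(seq)} vs {structure.length})"
            )
        records.append(StructuredSequence(rec_id, seq, structure))
        i += 3
    return records


def format_records(records: Sequence[StructuredSequence]) -> str:
    out = []
    for rec in records:
        out.append(f">{rec.id}\n{rec.sequence}\n{to_dotbracket(rec.structure)}\n")
    return "".join(out)


def read_records(path) -> list[StructuredSequence]:
    with open(path) as fh:
        return parse_records(fh.read())


def write_records(records: Sequence[StructuredSequence], path) -> None:
    with open(path, "w") as fh:
        fh.write(format_records(records))


def filter_dataset(
    records: Sequence[StructuredSequence], max_bp_similarity: float = 0.8
) -> list[StructuredSequence]:
    """Apply the standard benchmark-cleaning rules, preserving input order.

    Drops (a) pseudoknotted structures, (b) exact duplicate sequences (first
    occurrence kept), and (c) any record whose base-pair similarity to an
    already-retained record exceeds ``max_bp_similarity``.
    """
    if not 0.0 <= max_bp_similarity <= 1.0:
        raise ValueError("max_bp_similarity must be in [0, 1]")
    kept: list[StructuredSequence] = []
    seen_seqs: set[str] = set()
    for rec in records:
        if detect_pseudoknot(rec.structure.pairs):
            continue
        if rec.sequence in seen_seqs:
            continue
        if any(
            base_pair_similarity(rec.structure, prev.structure) > max_bp_similarity
            for prev in kept
        ):
            continue
        kept.append(rec)
        seen_seqs.add(rec.sequence)
    return kept
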