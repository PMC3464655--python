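"""Heuristic ambiguity and completeness testing.

Both properties are undecidable in general, so verdicts are heuristic:

* A grammar is **ambiguous** if some structure string has more than one
  derivation.  The test exhaustively counts derivations for every derivable
  string up to a short length, then samples longer derivable strings from
  uniform-rule stochastic derivations.  A positive verdict carries a witness;
  a negative verdict only holds up to the tested bound.
* A grammar is **complete** if it derives every valid structure whose hairpin
  loops all have at least two unpaired positions.  The test enumerates all
  such structures of length 2 up to a bound and checks derivability;
  single-position structures are exempt (a lone unpaired base carries no
  structural information, and several otherwise-complete grammars lack a
  direct unpaired rule at the start symbol).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grammar import (
    BUILTIN_NAMES,
    Grammar,
    RuleKind,
    ScfgParams,
    builtin_grammar,
    validate_normal_form,
)
from .parse import count_derivations
from .sample import sample_structure

__all__ = [
    "DiagnosisReport",
    "check_ambiguity",
    "check_completeness",
    "table3_report",
    "enumerate_hairpin2_structures",
]

POSITIVE = "POSITIVE"
NEGATIVE_UP_TO_BOUND = "NEGATIVE_UP_TO_BOUND"


@dataclass(frozen=True)
class DiagnosisReport:
    property: str  # "ambiguity" | "completeness"
    verdict: str  # POSITIVE | NEGATIVE_UP_TO_BOUND
    witnesses: tuple[str, ...] = ()
    bound: int = 0
    samples: int = 0

    @property
    def positive(self) -> bool:
        return self.verdict == POSITIVE


def _check_valid(grammar: Grammar) -> None:
    violations = validate_normal_form(grammar)
    if violations:
        raise ValueError("invalid grammar: " + "; ".join(violations))


def _derivation_count_sets(
    grammar: Grammar, max_len: int, cap: int = 2
) -> list[dict[str, int]]:
    """For each length, map derivable string -> derivation count (capped).

    Built bottom-up over lengths; children of every rule are strictly shorter
    than their parent span, so a single pass by increasing length suffices.
    """
    by_nt: dict[str, list[dict[str, int]]] = {
        nt: [dict() for _ in range(max_len + 1)] for nt in grammar.nonterminals
    }
    for length in range(1, max_len + 1):
        for rule in grammar.rules:
            target = by_nt[rule.lhs][length]
            if rule.kind is RuleKind.UNPAIRED:
                if length == 1:
                    target["."] = min(cap, target.get(".", 0) + 1)
            elif rule.kind is RuleKind.PAIR:
                if length >= 3:
                    for s, c in by_nt[rule.children[0]][length - 2].items():
                        key = f"({s})"
                        target[key] = min(cap, target.get(key, 0) + c)
            else:
                u, v = rule.children
                for l1 in range(1, length):
                    right = by_nt[v][length - l1]
                    if not right:
                        continue
                    for s1, c1 in by_nt[u][l1].items():
                        for s2, c2 in right.items():
                            key = s1 + s2
                            target[key] = min(cap, target.get(key, 0) + c1 * c2)
    return by_nt[grammar.start]


def check_ambiguity(
    grammar: Grammar,
    max_len: int = 30,
    sample_budget: int = 1000,
    rng: np.random.Generator | None = None,
) -> DiagnosisReport:
    """Heuristic ambiguity test: exhaustive to length min(max_len, 10), then
    sampled derivable structures up to ``max_len``.

    POSITIVE verdicts carry a witness structure with >= 2 derivations; a
    negative verdict is only "no ambiguity found up to the bound".
    """
    _check_valid(grammar)
    if rng is None:
        rng = np.random.default_rng(0)
    exhaustive_len = min(max_len, 10)
    counted = _derivation_count_sets(grammar, exhaustive_len)
    witnesses = sorted(
        (s for length in range(1, exhaustive_len + 1)
         for s, c in counted[length].items() if c >= 2),
        key=lambda s: (len(s), s),
    )
    if witnesses:
        return DiagnosisReport(
            "ambiguity", POSITIVE, tuple(witnesses[:5]), bound=exhaustive_len
        )
    uniform = ScfgParams.uniform(grammar)
    seen: set[str] = set()
    samples = 0
    for _ in range(sample_budget):
        text = sample_structure(grammar, uniform, rng, max_len)
        if text is None:
            continue
        samples += 1
        if text in seen or len(text) <= exhaustive_len:
            continue
        seen.add(text)
        if count_derivations(grammar, text, cap=2) >= 2:
            return DiagnosisReport(
                "ambiguity", POSITIVE, (text,), bound=max_len, samples=samples
            )
    return DiagnosisReport(
        "ambiguity", NEGATIVE_UP_TO_BOUND, (), bound=max_len, samples=samples
    )


def enumerate_hairpin2_structures(max_len: int) -> list[set[str]]:
    """All valid dot-bracket strings per length with every hairpin >= 2.

    Index ``l`` of the returned list holds the strings of length ``l``;
    built by the decomposition  W -> ε | . W | ( H ) W  with H any member of
    W of length >= 2.
    """
    W: list[set[str]] = [set() for _ in range(max_len + 1)]
    W[0].add("")
    for length in range(1, max_len + 1):
        bucket = W[length]
        for s in W[length - 1]:
            bucket.add("." + s)
        for inner_len in range(2, length - 1):
            tail_len = length - inner_len - 2
            for h in W[inner_len]:
                wrapped = f"({h})"
                for t in W[tail_len]:
                    bucket.add(wrapped + t)
    return W


def _derivable_strings(grammar: Grammar, max_len: int) -> list[set[str]]:
    """Strings derivable from the start symbol, per length."""
    by_nt: dict[str, list[set[str]]] = {
        nt: [set() for _ in range(max_len + 1)] for nt in grammar.nonterminals
    }
    for length in range(1, max_len + 1):
        for rule in grammar.rules:
            target = by_nt[rule.lhs][length]
            if rule.kind is RuleKind.UNPAIRED:
                if length == 1:
                    target.add(".")
            elif rule.kind is RuleKind.PAIR:
                if length >= 3:
                    target.update(f"({s})" for s in by_nt[rule.children[0]][length - 2])
            else:
                u, v = rule.children
                for l1 in range(1, length):
                    right = by_nt[v][length - l1]
                    if right:
                        for s1 in by_nt[u][l1]:
                            target.update(s1 + s2 for s2 in right)
    return by_nt[grammar.start]


def check_completeness(
    grammar: Grammar,
    max_len: int = 14,
    sample_budget: int = 0,
    rng: np.random.Generator | None = None,
    max_witnesses: int = 20,
) -> DiagnosisReport:
    """Heuristic completeness test over structures of length 2..max_len.

    POSITIVE means *incomplete*: some valid structure (all hairpins >= 2) has
    no derivation; the smallest such structures are returned as witnesses.
    ``max_len > 18`` is rejected (combinatorial explosion) unless a sampling
    budget is given, in which case random valid structures are spot-checked.
    """
    _check_valid(grammar)
    if max_len > 18 and not sample_budget:
        raise ValueError("max_len > 18 requires sampling mode (sample_budget > 0)")
    if sample_budget:
        if rng is None:
            rng = np.random.default_rng(0)
        samples = 0
        for _ in range(sample_budget):
            length = int(rng.integers(2, max_len + 1))
            text = _random_hairpin2_structure(rng, length)
            if text is None:
                continue
            samples += 1
            if count_derivations(grammar, text, cap=1) == 0:
                return DiagnosisReport(
                    "completeness", POSITIVE, (text,), bound=max_len, samples=samples
                )
        return DiagnosisReport(
            "completeness", NEGATIVE_UP_TO_BOUND, (), bound=max_len, samples=samples
        )
    valid = enumerate_hairpin2_structures(max_len)
    derivable = _derivable_strings(grammar, max_len)
    witnesses: list[str] = []
    for length in range(2, max_len + 1):
        missing = valid[length] - derivable[length]
        if missing:
            witnesses.extend(sorted(missing)[: max_witnesses - len(witnesses)])
            if len(witnesses) >= max_witnesses:
                break
    if witnesses:
        return DiagnosisReport(
            "completeness", POSITIVE, tuple(witnesses), bound=max_len
        )
    return DiagnosisReport("completeness", NEGATIVE_UP_TO_BOUND, (), bound=max_len)


def _random_hairpin2_structure(rng: np.random.Generator, length: int) -> str | None:
    if length < 0:
        return None
    if length == 0:
        return ""
    options = ["dot"] if length >= 1 else []
    if length >= 4:
        options.append("pair")
    choice = options[int(rng.integers(len(options)))]
    if choice == "dot":
        rest = _random_hairpin2_structure(rng, length - 1)
        return None if rest is None else "." + rest
    inner_len = int(rng.integers(2, length - 1))
    inner = _random_hairpin2_structure(rng, inner_len)
    tail = _random_hairpin2_structure(rng, length - inner_len - 2)
    if inner is None or tail is None:
        return None
    return f"({inner})" + tail


def table3_report(
    grammar_names: Sequence[str] = BUILTIN_NAMES,
    max_len: int = 14,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, bool, bool]]:
    """Ambiguity/completeness verdicts for the bundled grammars.

    Returns ``(name, ambiguous, complete)`` rows using the default heuristic
    bounds (ambiguity: exhaustive to 10, sampled to 30; completeness:
    exhaustive to ``max_len``).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for name in grammar_names:
        grammar = builtin_grammar(name)
        amb = check_ambiguity(grammar, rng=rng)
        comp = check_completeness(grammar, max_len=max_len)
        rows.append((name, amb.positive, not comp.positive))
    return rows
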