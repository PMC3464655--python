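"""Grammars in the double emission normal form, their parameters, and text I/O.

A structure-generating grammar here is a context-free grammar over the terminal
alphabet ``{ ( , ) , . }`` whose productions are restricted to three shapes:

    T -> U V        (BRANCH: bifurcation)
    T -> .          (UNPAIRED: emit one unpaired position)
    T -> ( U )      (PAIR: emit both partners of a base pair at once)

The pair rule emits the two parenthesis terminals simultaneously — hence
"double emission" — which lets a single production carry the 16-way paired
nucleotide distribution when the grammar is made stochastic.  Epsilon rules
(``T -> ε``) and unit rules (``T -> U``) are excluded: they admit cyclic
derivations and a countably infinite number of parses for some strings.

For ``m`` non-terminals there are ``m^3`` BRANCH, ``m^2`` PAIR and ``m``
UNPAIRED rules, so the space of grammars has size ``2^(m^3 + m^2 + m)``.

An :class:`ScfgParams` attaches a probability distribution over each
non-terminal's rules plus two global emission tables: a 4-way distribution for
unpaired nucleotides and a 16-way distribution over ordered base pairs.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "RuleKind",
    "ProductionRule",
    "Grammar",
    "ScfgParams",
    "GrammarFormatError",
    "branch",
    "unpaired",
    "pair",
    "validate_normal_form",
    "count_grammar_space",
    "all_normal_form_rules",
    "addable_rules",
    "builtin_grammar",
    "builtin_grammar_names",
    "read_grammar",
    "write_grammar",
    "loads_grammar",
    "dumps_grammar",
    "BASES",
    "BASE_PAIRS",
]

BASES = ("A", "C", "G", "U")
BASE_PAIRS = tuple((a, b) for a in BASES for b in BASES)

BUILTIN_NAMES = ("KH99p", "GG1", "GG2", "GG3", "GG4", "GG5", "GG6")

_PROB_TOL = 1e-9


class RuleKind(enum.Enum):
    BRANCH = "branch"      # T -> U V
    UNPAIRED = "unpaired"  # T -> .
    PAIR = "pair"          # T -> ( U )
    # Shapes outside the normal form, representable so validation can name them:
    UNIT = "unit"          # T -> U
    EPSILON = "epsilon"    # T -> ε

    def __lt__(self, other):  # deterministic rule sorting
        if isinstance(other, RuleKind):
            return self.value < other.value
        return NotImplemented


class ProductionRule(NamedTuple):
    lhs: str
    kind: RuleKind
    children: tuple[str, ...]

    def __str__(self) -> str:
        if self.kind is RuleKind.BRANCH:
            return f"{self.lhs} -> {self.children[0]} {self.children[1]}"
        if self.kind is RuleKind.UNPAIRED:
            return f"{self.lhs} -> ."
        if self.kind is RuleKind.PAIR:
            return f"{self.lhs} -> ( {self.children[0]} )"
        if self.kind is RuleKind.UNIT:
            return f"{self.lhs} -> {self.children[0]}"
        return f"{self.lhs} -> ε"


def branch(lhs: str, u: str, v: str) -> ProductionRule:
    return ProductionRule(lhs, RuleKind.BRANCH, (u, v))


def unpaired(lhs: str) -> ProductionRule:
    return ProductionRule(lhs, RuleKind.UNPAIRED, ())


def pair(lhs: str, u: str) -> ProductionRule:
    return ProductionRule(lhs, RuleKind.PAIR, (u,))


_EXPECTED_ARITY = {
    RuleKind.BRANCH: 2,
    RuleKind.UNPAIRED: 0,
    RuleKind.PAIR: 1,
    RuleKind.UNIT: 1,
    RuleKind.EPSILON: 0,
}


@dataclass(frozen=True)
class Grammar:
    """A grammar in (or to be validated against) the double emission normal form.

    ``rules`` is an ordered tuple — rule order is used for deterministic
    tie-breaking in parsing — but grammar equality is order-insensitive in
    both the rule list and the non-terminal list (and sensitive to symbol
    names and the start symbol).
    """

    nonterminals: tuple[str, ...]
    start: str
    rules: tuple[ProductionRule, ...]

    def __post_init__(self) -> None:
        if len(set(self.nonterminals)) != len(self.nonterminals):
            raise ValueError("duplicate non-terminal names")
        if len(set(self.rules)) != len(self.rules):
            raise ValueError("duplicate production rules")

    def rules_for(self, nt: str) -> tuple[ProductionRule, ...]:
        return tuple(r for r in self.rules if r.lhs == nt)

    def with_rules(self, rules: Iterable[ProductionRule]) -> "Grammar":
        return Grammar(self.nonterminals, self.start, tuple(rules))

    def add_rule(self, rule: ProductionRule) -> "Grammar":
        return self.with_rules(self.rules + (rule,))

    def remove_rule(self, rule: ProductionRule) -> "Grammar":
        return self.with_rules(r for r in self.rules if r != rule)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Grammar):
            return NotImplemented
        return (
            self.start == other.start
            and set(self.nonterminals) == set(other.nonterminals)
            and set(self.rules) == set(other.rules)
        )

    def __hash__(self) -> int:
        return hash((self.start, frozenset(self.nonterminals), frozenset(self.rules)))

    def canonical_key(self) -> tuple:
        """A hashable, order-insensitive identity key (for caches)."""
        return (
            self.start,
            frozenset(self.nonterminals),
            frozenset(self.rules),
        )

    def __str__(self) -> str:
        return dumps_grammar(self)


@dataclass
class ScfgParams:
    """Rule probabilities plus global unpaired (4-way) and paired (16-way) emissions."""

    rule_prob: dict[ProductionRule, float]
    unpaired_emit: dict[str, float]
    paired_emit: dict[tuple[str, str], float]

    @classmethod
    def uniform(cls, grammar: Grammar) -> "ScfgParams":
        rule_prob: dict[ProductionRule, float] = {}
        for nt in grammar.nonterminals:
            rules = grammar.rules_for(nt)
            for r in rules:
                rule_prob[r] = 1.0 / len(rules)
        return cls(
            rule_prob=rule_prob,
            unpaired_emit={b: 0.25 for b in BASES},
            paired_emit={bp: 1.0 / 16.0 for bp in BASE_PAIRS},
        )

    def validate(self, grammar: Grammar, tol: float = _PROB_TOL) -> None:
        for nt in grammar.nonterminals:
            rules = grammar.rules_for(nt)
            if not rules:
                continue
            total = 0.0
            for r in rules:
                p = self.rule_prob.get(r)
                if p is None:
                    raise ValueError(f"missing probability for rule {r}")
                if p < 0:
                    raise ValueError(f"negative probability for rule {r}")
                total += p
            if abs(total - 1.0) > tol:
                raise ValueError(
                    f"rule probabilities of {nt} sum to {total}, not 1"
                )
        for name, table, keys in (
            ("unpaired_emit", self.unpaired_emit, BASES),
            ("paired_emit", self.paired_emit, BASE_PAIRS),
        ):
            total = 0.0
            for k in keys:
                p = table.get(k)
                if p is None:
                    raise ValueError(f"missing {name} entry {k}")
                if p < 0:
                    raise ValueError(f"negative {name} entry {k}")
                total += p
            if abs(total - 1.0) > tol:
                raise ValueError(f"{name} sums to {total}, not 1")


def validate_normal_form(grammar: Grammar) -> list[str]:
    """Return a list of violation descriptions; empty iff the grammar is valid.

    Checks: start symbol membership, symbol closure, the three normal-form rule
    shapes (unit and epsilon rules are named violations), arity consistency,
    and a productive start symbol (at least one rule).
    """
    violations: list[str] = []
    nts = set(grammar.nonterminals)
    if grammar.start not in nts:
        violations.append(f"start symbol {grammar.start!r} not a non-terminal")
    for rule in grammar.rules:
        if rule.lhs not in nts:
            violations.append(f"rule {rule}: unknown left-hand side {rule.lhs!r}")
        if len(rule.children) != _EXPECTED_ARITY[rule.kind]:
            violations.append(f"rule {rule}: wrong arity for {rule.kind.value}")
            continue
        for child in rule.children:
            if child not in nts:
                violations.append(f"rule {rule}: unknown symbol {child!r}")
        if rule.kind is RuleKind.UNIT:
            violations.append(f"rule {rule}: unit rules are not in the normal form")
        elif rule.kind is RuleKind.EPSILON:
            violations.append(f"rule {rule}: epsilon rules are not in the normal form")
    if grammar.start in nts and not grammar.rules_for(grammar.start):
        violations.append(f"unproductive start: {grammar.start!r} has no rules")
    return violations


def count_grammar_space(m: int) -> int:
    """Number of grammars over ``m`` non-terminals: ``2^(m^3 + m^2 + m)``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 2 ** (m**3 + m**2 + m)


def all_normal_form_rules(nonterminals: Sequence[str]) -> list[ProductionRule]:
    """All ``m^3 + m^2 + m`` normal-form rules over the given non-terminals."""
    rules: list[ProductionRule] = []
    for t in nonterminals:
        rules.append(unpaired(t))
        for u in nonterminals:
            rules.append(pair(t, u))
        for u, v in itertools.product(nonterminals, repeat=2):
            rules.append(branch(t, u, v))
    return rules


def addable_rules(grammar: Grammar) -> set[ProductionRule]:
    """Normal-form rules over the grammar's non-terminals not already present."""
    violations = validate_normal_form(grammar)
    if violations:
        raise ValueError("invalid grammar: " + "; ".join(violations))
    return set(all_normal_form_rules(grammar.nonterminals)) - set(grammar.rules)


# ---------------------------------------------------------------------------
# Text format


class GrammarFormatError(ValueError):
    """Syntax or consistency error in grammar text, with a line number."""


def _parse_alternative(tokens: list[str], lhs: str, lineno: int):
    prob = None
    if tokens and tokens[-1].startswith("[") and tokens[-1].endswith("]"):
        try:
            prob = float(tokens[-1][1:-1])
        except ValueError as exc:
            raise GrammarFormatError(
                f"line {lineno}: bad probability {tokens[-1]!r}"
            ) from exc
        tokens = tokens[:-1]
    if tokens == ["."]:
        return unpaired(lhs), prob
    if len(tokens) == 3 and tokens[0] == "(" and tokens[2] == ")":
        return pair(lhs, tokens[1]), prob
    if len(tokens) == 2 and "(" not in tokens and ")" not in tokens:
        return branch(lhs, tokens[0], tokens[1]), prob
    if len(tokens) == 1:
        raise GrammarFormatError(
            f"line {lineno}: unit rule {lhs} -> {tokens[0]} is not in the normal form"
        )
    if not tokens:
        raise GrammarFormatError(
            f"line {lineno}: empty (epsilon) alternative for {lhs} is not in the normal form"
        )
    raise GrammarFormatError(
        f"line {lineno}: alternative {' '.join(tokens)!r} for {lhs} does not match "
        "'U V', '.', or '( U )'"
    )


def loads_grammar(text: str) -> tuple[Grammar, ScfgParams | None]:
    """Parse the grammar text format.  Returns (grammar, params or None).

    Format: optional ``#`` comments; one ``start: <sym>`` line; one line per
    non-terminal ``<sym> -> alt | alt | ...`` with whitespace-separated tokens
    and optional ``[p]`` probability suffixes; optional ``unpaired:`` and
    ``paired:`` emission lines.
    """
    start: str | None = None
    nonterminals: list[str] = []
    rules: list[ProductionRule] = []
    rule_prob: dict[ProductionRule, float] = {}
    any_prob = False
    unpaired_emit: dict[str, float] | None = None
    paired_emit: dict[tuple[str, str], float] | None = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("start:"):
            start = line[len("start:"):].strip()
            if not start or len(start.split()) != 1:
                raise GrammarFormatError(f"line {lineno}: bad start declaration")
            continue
        if line.startswith("unpaired:"):
            toks = line[len("unpaired:"):].split()
            if len(toks) != 8:
                raise GrammarFormatError(
                    f"line {lineno}: unpaired block needs 4 base/probability pairs"
                )
            unpaired_emit = {}
            for b, p in zip(toks[::2], toks[1::2]):
                if b not in BASES:
                    raise GrammarFormatError(f"line {lineno}: unknown base {b!r}")
                unpaired_emit[b] = float(p)
            continue
        if line.startswith("paired:"):
            toks = line[len("paired:"):].split()
            if len(toks) != 32:
                raise GrammarFormatError(
                    f"line {lineno}: paired block needs 16 pair/probability entries"
                )
            paired_emit = {}
            for bp, p in zip(toks[::2], toks[1::2]):
                if len(bp) != 2 or (bp[0], bp[1]) not in BASE_PAIRS:
                    raise GrammarFormatError(f"line {lineno}: unknown base pair {bp!r}")
                paired_emit[(bp[0], bp[1])] = float(p)
            continue
        if "->" not in line:
            raise GrammarFormatError(f"line {lineno}: expected '<sym> -> ...'")
        lhs_text, rhs_text = line.split("->", 1)
        lhs = lhs_text.strip()
        if not lhs or len(lhs.split()) != 1:
            raise GrammarFormatError(f"line {lineno}: bad left-hand side {lhs!r}")
        if lhs not in nonterminals:
            nonterminals.append(lhs)
        for alt in rhs_text.split("|"):
            rule, prob = _parse_alternative(alt.split(), lhs, lineno)
            if rule in rule_prob or rule in rules:
                raise GrammarFormatError(f"line {lineno}: duplicate rule {rule}")
            rules.append(rule)
            if prob is not None:
                any_prob = True
                rule_prob[rule] = prob

    if start is None:
        raise GrammarFormatError("missing 'start:' declaration")
    for rule in rules:
        for child in rule.children:
            if child not in nonterminals:
                nonterminals.append(child)
    if start not in nonterminals:
        nonterminals.append(start)
    grammar = Grammar(tuple(nonterminals), start, tuple(rules))

    params: ScfgParams | None = None
    if any_prob or unpaired_emit is not None or paired_emit is not None:
        if not all(r in rule_prob for r in rules):
            missing = [str(r) for r in rules if r not in rule_prob]
            raise GrammarFormatError(
                "probabilities present but missing for: " + ", ".join(missing)
            )
        if unpaired_emit is None:
            unpaired_emit = {b: 0.25 for b in BASES}
        if paired_emit is None:
            paired_emit = {bp: 1.0 / 16.0 for bp in BASE_PAIRS}
        params = ScfgParams(rule_prob, unpaired_emit, paired_emit)
        try:
            params.validate(grammar, tol=1e-6)
        except ValueError as exc:
            raise GrammarFormatError(str(exc)) from exc
    return grammar, params


def _fmt(p: float) -> str:
    return format(p, ".17g")


def dumps_grammar(grammar: Grammar, params: ScfgParams | None = None) -> str:
    lines = [f"start: {grammar.start}"]
    for nt in grammar.nonterminals:
        rules = grammar.rules_for(nt)
        if not rules:
            continue
        alts = []
        for r in rules:
            if r.kind is RuleKind.BRANCH:
                alt = f"{r.children[0]} {r.children[1]}"
            elif r.kind is RuleKind.UNPAIRED:
                alt = "."
            else:
                alt = f"( {r.children[0]} )"
            if params is not None:
                alt += f" [{_fmt(params.rule_prob[r])}]"
            alts.append(alt)
        lines.append(f"{nt} -> " + " | ".join(alts))
    if params is not None:
        lines.append(
            "unpaired: " + " ".join(f"{b} {_fmt(params.unpaired_emit[b])}" for b in BASES)
        )
        lines.append(
            "paired: "
            + " ".join(f"{a}{b} {_fmt(params.paired_emit[(a, b)])}" for a, b in BASE_PAIRS)
        )
    return "\n".join(lines) + "\n"


def read_grammar(path) -> tuple[Grammar, ScfgParams | None]:
    with open(path) as fh:
        return loads_grammar(fh.read())


def write_grammar(grammar: Grammar, path, params: ScfgParams | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_grammar(grammar, params))


# ---------------------------------------------------------------------------
# Bundled grammars


def builtin_grammar_names() -> tuple[str, ...]:
    return BUILTIN_NAMES


def builtin_grammar(name: str, with_params: bool = False):
    """Load a bundled grammar by name (KH99p, GG1..GG6).

    KH99p is the Knudsen–Hein Pfold grammar re-expressed in the double
    emission normal form; GG1–GG6 are grammars discovered by evolutionary and
    local search.  With ``with_params=True`` returns ``(grammar, params)``
    where params is None unless a parameterised fixture is bundled.
    """
    key = name.replace("'", "p").replace("′", "p")
    if key not in BUILTIN_NAMES and key != "KH99p_synthetic":
        raise KeyError(f"unknown builtin grammar {name!r}; know {BUILTIN_NAMES}")
    text = (
        resources.files("rnascfg").joinpath(f"grammars/{key}.grm").read_text()
    )
    grammar, params = loads_grammar(text)
    if with_params:
        return grammar, params
    return grammar
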