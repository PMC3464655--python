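"""Dynamic programs over double-emission-normal-form grammars.

Two families of DP run over the same grammar:

* structure-level: the input is a dot-bracket string; terminals are matched
  literally (UNPAIRED rules consume ``.``, PAIR rules consume a ``(`` / ``)``
  at the two span ends).  Used for derivation counting/sampling and for
  supervised training.
* sequence-level: the input is a nucleotide string; UNPAIRED rules emit a
  base from the 4-way table and PAIR rules emit the span's two end bases
  jointly from the 16-way table.  Used for CYK decoding, likelihoods, and
  posterior base-pair probabilities via inside-outside.

Spans are half-open ``[i, j)`` and 0-based.  All sequence-level DPs run in log
space with ``-inf`` encoding impossibility; ``NO_PARSE`` is represented by the
value ``None``, never an exception.  Complexity is O(|rules| n^3) time and
O(|N| n^2) space, with the split-point loops vectorised.

CYK tie-breaking is deterministic: PAIR/UNPAIRED rules in grammar order first,
then split points ``k`` ascending, then BRANCH rules in grammar order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .grammar import BASES, Grammar, ProductionRule, RuleKind, ScfgParams
from .structure import parse_dotbracket

__all__ = [
    "Derivation",
    "PosteriorMatrix",
    "structure_cyk",
    "count_derivations",
    "sample_derivation",
    "sequence_inside",
    "sequence_cyk",
    "sequence_outside",
    "sequence_outside_posteriors",
    "sequence_expected_counts",
    "derivable_lengths",
]

_NEG_INF = -np.inf
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_EXACT_CAP = 2**52  # float64 counts below this are exact integers


@dataclass(frozen=True)
class Derivation:
    """A node of a derivation tree: a rule applied to span ``[i, j)``."""

    rule: ProductionRule
    i: int
    j: int
    children: tuple["Derivation", ...] = ()

    def iter_nodes(self) -> Iterator["Derivation"]:
        yield self
        for child in self.children:
            yield from child.iter_nodes()

    def rule_multiset(self) -> dict[ProductionRule, int]:
        counts: dict[ProductionRule, int] = {}
        for node in self.iter_nodes():
            counts[node.rule] = counts.get(node.rule, 0) + 1
        return counts

    def to_dotbracket(self) -> str:
        if self.rule.kind is RuleKind.UNPAIRED:
            return "."
        if self.rule.kind is RuleKind.PAIR:
            return "(" + self.children[0].to_dotbracket() + ")"
        return self.children[0].to_dotbracket() + self.children[1].to_dotbracket()

    def log_probability(self, params: ScfgParams) -> float:
        total = 0.0
        for node in self.iter_nodes():
            total += float(np.log(params.rule_prob[node.rule]))
        return total


@dataclass
class PosteriorMatrix:
    """Posterior base-pairing probabilities p(i,j) and unpaired q(i).

    ``pair_prob[i, j]`` (i < j) is the posterior probability that positions i
    and j are paired; ``unpaired_prob[i] = 1 - sum_j pair_prob``.
    """

    pair_prob: np.ndarray  # (n, n), upper triangle
    unpaired_prob: np.ndarray  # (n,)

    @property
    def n(self) -> int:
        return len(self.unpaired_prob)


class _Compiled:
    """Grammar flattened to integer-indexed rule arrays for vectorised DP."""

    def __init__(self, grammar: Grammar, params: ScfgParams | None = None):
        self.grammar = grammar
        self.nts = grammar.nonterminals
        self.index = {nt: k for k, nt in enumerate(self.nts)}
        self.n_nt = len(self.nts)
        self.start = self.index[grammar.start]

        b_t, b_u, b_v, b_rules = [], [], [], []
        p_t, p_u, p_rules = [], [], []
        u_t, u_rules = [], []
        for rule in grammar.rules:
            if rule.kind is RuleKind.BRANCH:
                b_t.append(self.index[rule.lhs])
                b_u.append(self.index[rule.children[0]])
                b_v.append(self.index[rule.children[1]])
                b_rules.append(rule)
            elif rule.kind is RuleKind.PAIR:
                p_t.append(self.index[rule.lhs])
                p_u.append(self.index[rule.children[0]])
                p_rules.append(rule)
            elif rule.kind is RuleKind.UNPAIRED:
                u_t.append(self.index[rule.lhs])
                u_rules.append(rule)
            else:
                raise ValueError(f"rule {rule} is not in the normal form")
        self.b_t = np.asarray(b_t, dtype=np.intp)
        self.b_u = np.asarray(b_u, dtype=np.intp)
        self.b_v = np.asarray(b_v, dtype=np.intp)
        self.b_rules = tuple(b_rules)
        self.p_t = np.asarray(p_t, dtype=np.intp)
        self.p_u = np.asarray(p_u, dtype=np.intp)
        self.p_rules = tuple(p_rules)
        self.u_t = np.asarray(u_t, dtype=np.intp)
        self.u_rules = tuple(u_rules)

        if params is not None:
            with np.errstate(divide="ignore"):
                self.b_logp = np.log(
                    np.asarray([params.rule_prob[r] for r in b_rules], dtype=float)
                ) if b_rules else np.empty(0)
                self.p_logp = np.log(
                    np.asarray([params.rule_prob[r] for r in p_rules], dtype=float)
                ) if p_rules else np.empty(0)
                self.u_logp = np.log(
                    np.asarray([params.rule_prob[r] for r in u_rules], dtype=float)
                ) if u_rules else np.empty(0)
                self.emit_u = np.log(
                    np.asarray([params.unpaired_emit[b] for b in BASES], dtype=float)
                )
                self.emit_p = np.log(
                    np.asarray(
                        [[params.paired_emit[(a, b)] for b in BASES] for a in BASES],
                        dtype=float,
                    )
                )
        else:
            self.b_logp = np.zeros(len(b_rules))
            self.p_logp = np.zeros(len(p_rules))
            self.u_logp = np.zeros(len(u_rules))
            self.emit_u = np.zeros(4)
            self.emit_p = np.zeros((4, 4))


def _encode_sequence(sequence: str) -> np.ndarray:
    try:
        return np.asarray([_BASE_INDEX[c] for c in sequence.upper()], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"sequence contains non-ACGU character {exc}") from None


# ---------------------------------------------------------------------------
# Structure-level DP (terminal string over '(', ')', '.')


def _structure_count_tables(cg: _Compiled, s: str, cap: float) -> np.ndarray:
    """Derivation-count table C[nt, i, j], saturating at ``cap`` per cell."""
    n = len(s)
    C = np.zeros((cg.n_nt, n + 1, n + 1))
    is_dot = np.asarray([c == "." for c in s])
    for i in range(n):
        if is_dot[i]:
            C[cg.u_t, i, i + 1] = 1.0
    for length in range(2, n + 1):
        for i in range(n - length + 1):
            j = i + length
            cell = np.zeros(cg.n_nt)
            if length >= 3 and s[i] == "(" and s[j - 1] == ")" and len(cg.p_t):
                np.add.at(cell, cg.p_t, C[cg.p_u, i + 1, j - 1])
            if len(cg.b_t):
                ks = np.arange(i + 1, j)
                left = C[cg.b_u[:, None], i, ks[None, :]]
                right = C[cg.b_v[:, None], ks[None, :], j]
                np.add.at(cell, cg.b_t, (left * right).sum(axis=1))
            C[:, i, j] = np.minimum(cell, cap)
    return C


def count_derivations(grammar: Grammar, structure_text: str, cap: int = 10**9) -> int:
    """Number of distinct derivations of a dot-bracket string, saturating at cap."""
    parse_dotbracket(structure_text)  # validates balance
    n = len(structure_text)
    if n == 0:
        return 0
    cg = _Compiled(grammar)
    C = _structure_count_tables(cg, structure_text, float(cap))
    return int(min(C[cg.start, 0, n], cap))


def _structure_options(cg: _Compiled, C: np.ndarray, s: str, nt: int, i: int, j: int):
    """Enumerate (rule, split, weight) options at a cell, in tie-break order.

    ``weight`` is the number of derivations through the option (product of
    child counts); options with weight 0 are omitted.
    """
    length = j - i
    options = []
    if length == 1 and s[i] == ".":
        for t, rule in zip(cg.u_t, cg.u_rules):
            if t == nt:
                options.append((rule, None, 1.0))
        return options
    if length >= 3 and s[i] == "(" and s[j - 1] == ")":
        for t, u, rule in zip(cg.p_t, cg.p_u, cg.p_rules):
            if t == nt:
                w = C[u, i + 1, j - 1]
                if w > 0:
                    options.append((rule, None, w))
    for k in range(i + 1, j):
        for t, u, v, rule in zip(cg.b_t, cg.b_u, cg.b_v, cg.b_rules):
            if t == nt:
                w = C[u, i, k] * C[v, k, j]
                if w > 0:
                    options.append((rule, k, w))
    return options


def _backtrack_structure(
    cg: _Compiled, C: np.ndarray, s: str, nt: int, i: int, j: int, chooser
) -> Derivation:
    options = _structure_options(cg, C, s, nt, i, j)
    rule, k, _ = options[chooser(options)]
    if rule.kind is RuleKind.UNPAIRED:
        return Derivation(rule, i, j)
    if rule.kind is RuleKind.PAIR:
        child = _backtrack_structure(
            cg, C, s, cg.index[rule.children[0]], i + 1, j - 1, chooser
        )
        return Derivation(rule, i, j, (child,))
    left = _backtrack_structure(cg, C, s, cg.index[rule.children[0]], i, k, chooser)
    right = _backtrack_structure(cg, C, s, cg.index[rule.children[1]], k, j, chooser)
    return Derivation(rule, i, j, (left, right))


def structure_cyk(
    grammar: Grammar, structure_text: str, params: ScfgParams | None = None
):
    """Best derivation of a dot-bracket string: ``(log-prob, Derivation)`` or None.

    With ``params`` the derivation probability (product of rule probabilities;
    emissions play no role at structure level) is maximised.  Without params
    any single derivation is returned, with log-probability reported as 0.0.
    """
    parse_dotbracket(structure_text)
    n = len(structure_text)
    if n == 0:
        return None
    cg = _Compiled(grammar, params)
    if params is None:
        C = _structure_count_tables(cg, structure_text, float(_EXACT_CAP))
        if C[cg.start, 0, n] <= 0:
            return None
        deriv = _backtrack_structure(
            cg, C, structure_text, cg.start, 0, n, lambda opts: 0
        )
        return 0.0, deriv

    s = structure_text
    L = np.full((cg.n_nt, n + 1, n + 1), _NEG_INF)
    for i in range(n):
        if s[i] == ".":
            L[cg.u_t, i, i + 1] = cg.u_logp
    for length in range(2, n + 1):
        for i in range(n - length + 1):
            j = i + length
            cell = np.full(cg.n_nt, _NEG_INF)
            if length >= 3 and s[i] == "(" and s[j - 1] == ")" and len(cg.p_t):
                np.maximum.at(cell, cg.p_t, cg.p_logp + L[cg.p_u, i + 1, j - 1])
            if len(cg.b_t):
                ks = np.arange(i + 1, j)
                left = L[cg.b_u[:, None], i, ks[None, :]]
                right = L[cg.b_v[:, None], ks[None, :], j]
                np.maximum.at(
                    cell, cg.b_t, ((cg.b_logp[:, None] + left) + right).max(axis=1)
                )
            L[:, i, j] = cell
    best = L[cg.start, 0, n]
    if best == _NEG_INF:
        return None
    deriv = _backtrack_weighted_structure(cg, L, s, cg.start, 0, n)
    return float(best), deriv


def _backtrack_weighted_structure(
    cg: _Compiled, L: np.ndarray, s: str, nt: int, i: int, j: int
) -> Derivation:
    length = j - i
    if length == 1:
        for t, logp, rule in zip(cg.u_t, cg.u_logp, cg.u_rules):
            if t == nt and s[i] == ".":
                return Derivation(rule, i, j)
        raise AssertionError("backtrack reached an underivable unit cell")
    target = L[nt, i, j]
    # PAIR options first, then k ascending x branch rules in grammar order.
    if length >= 3 and s[i] == "(" and s[j - 1] == ")":
        for t, u, logp, rule in zip(cg.p_t, cg.p_u, cg.p_logp, cg.p_rules):
            if t == nt and logp + L[u, i + 1, j - 1] == target:
                child = _backtrack_weighted_structure(cg, L, s, u, i + 1, j - 1)
                return Derivation(rule, i, j, (child,))
    for k in range(i + 1, j):
        for t, u, v, logp, rule in zip(cg.b_t, cg.b_u, cg.b_v, cg.b_logp, cg.b_rules):
            if t == nt and (logp + L[u, i, k]) + L[v, k, j] == target:
                left = _backtrack_weighted_structure(cg, L, s, u, i, k)
                right = _backtrack_weighted_structure(cg, L, s, v, k, j)
                return Derivation(rule, i, j, (left, right))
    raise AssertionError("backtrack failed to reproduce the table value")


def sample_derivation(
    grammar: Grammar, structure_text: str, rng: np.random.Generator
) -> Derivation:
    """Sample a derivation of a dot-bracket string uniformly at random.

    Weights come from the derivation-count tables during backtracking.  Counts
    above 2^52 are saturated, so the law is uniform up to that saturation.
    """
    parse_dotbracket(structure_text)
    n = len(structure_text)
    cg = _Compiled(grammar)
    if n == 0:
        raise ValueError("empty strings are not derivable")
    C = _structure_count_tables(cg, structure_text, float(_EXACT_CAP))
    if C[cg.start, 0, n] <= 0:
        raise ValueError(f"structure {structure_text!r} is not derivable")

    def chooser(options):
        if len(options) == 1:
            return 0
        weights = np.asarray([w for _, _, w in options])
        return int(rng.choice(len(options), p=weights / weights.sum()))

    return _backtrack_structure(cg, C, structure_text, cg.start, 0, n, chooser)


# ---------------------------------------------------------------------------
# Sequence-level DP (inside, CYK, outside, posteriors, expected counts)


def _inside_tables(cg: _Compiled, x: np.ndarray, mode: str) -> np.ndarray:
    """Inside ('sum') or Viterbi ('max') log tables I[nt, i, j]."""
    n = len(x)
    combine_reduce = np.logaddexp.reduce if mode == "sum" else np.max
    combine_at = np.logaddexp.at if mode == "sum" else np.maximum.at
    I = np.full((cg.n_nt, n + 1, n + 1), _NEG_INF)
    for i in range(n):
        I[cg.u_t, i, i + 1] = cg.u_logp + cg.emit_u[x[i]]
    for length in range(2, n + 1):
        for i in range(n - length + 1):
            j = i + length
            cell = np.full(cg.n_nt, _NEG_INF)
            if length >= 3 and len(cg.p_t):
                vals = (cg.p_logp + cg.emit_p[x[i], x[j - 1]]) + I[cg.p_u, i + 1, j - 1]
                combine_at(cell, cg.p_t, vals)
            if len(cg.b_t):
                ks = np.arange(i + 1, j)
                left = I[cg.b_u[:, None], i, ks[None, :]]
                right = I[cg.b_v[:, None], ks[None, :], j]
                scores = (cg.b_logp[:, None] + left) + right
                combine_at(cell, cg.b_t, combine_reduce(scores, axis=1))
            I[:, i, j] = cell
    return I


def sequence_inside(grammar: Grammar, params: ScfgParams, sequence: str):
    """Inside table and total log-likelihood log P(sequence | grammar, params).

    The total sums over all derivations; a sequence outside the grammar's
    support gets -inf (not an exception).
    """
    x = _encode_sequence(sequence)
    if len(x) == 0:
        return None, _NEG_INF
    cg = _Compiled(grammar, params)
    I = _inside_tables(cg, x, "sum")
    return I, float(I[cg.start, 0, len(x)])


def sequence_cyk(grammar: Grammar, params: ScfgParams, sequence: str):
    """Most likely derivation: ``(log-prob, Derivation, Structure)`` or None."""
    x = _encode_sequence(sequence)
    n = len(x)
    if n == 0:
        return None
    cg = _Compiled(grammar, params)
    V = _inside_tables(cg, x, "max")
    best = V[cg.start, 0, n]
    if best == _NEG_INF:
        return None
    deriv = _backtrack_sequence(cg, V, x, cg.start, 0, n)
    structure = parse_dotbracket(deriv.to_dotbracket())
    return float(best), deriv, structure


def _backtrack_sequence(
    cg: _Compiled, V: np.ndarray, x: np.ndarray, nt: int, i: int, j: int
) -> Derivation:
    length = j - i
    if length == 1:
        for t, rule in zip(cg.u_t, cg.u_rules):
            if t == nt:
                return Derivation(rule, i, j)
        raise AssertionError("backtrack reached an underivable unit cell")
    target = V[nt, i, j]
    if length >= 3:
        for t, u, logp, rule in zip(cg.p_t, cg.p_u, cg.p_logp, cg.p_rules):
            if t == nt:
                if (logp + cg.emit_p[x[i], x[j - 1]]) + V[u, i + 1, j - 1] == target:
                    child = _backtrack_sequence(cg, V, x, u, i + 1, j - 1)
                    return Derivation(rule, i, j, (child,))
    for k in range(i + 1, j):
        for t, u, v, logp, rule in zip(cg.b_t, cg.b_u, cg.b_v, cg.b_logp, cg.b_rules):
            if t == nt and (logp + V[u, i, k]) + V[v, k, j] == target:
                left = _backtrack_sequence(cg, V, x, u, i, k)
                right = _backtrack_sequence(cg, V, x, v, k, j)
                return Derivation(rule, i, j, (left, right))
    raise AssertionError("backtrack failed to reproduce the table value")


def _outside_tables(cg: _Compiled, x: np.ndarray, I: np.ndarray) -> np.ndarray:
    n = len(x)
    O = np.full((cg.n_nt, n + 1, n + 1), _NEG_INF)
    O[cg.start, 0, n] = 0.0
    for length in range(n - 1, 0, -1):
        for i in range(n - length + 1):
            j = i + length
            cell = O[:, i, j].copy()
            # child of a PAIR rule: parent spans [i-1, j+1)
            if i >= 1 and j + 1 <= n and len(cg.p_t):
                vals = (
                    O[cg.p_t, i - 1, j + 1]
                    + (cg.p_logp + cg.emit_p[x[i - 1], x[j]])
                )
                np.logaddexp.at(cell, cg.p_u, vals)
            if len(cg.b_t):
                # left child U of T -> U V: parents [i, jp), sibling [j, jp)
                if j + 1 <= n:
                    js = np.arange(j + 1, n + 1)
                    parent = O[cg.b_t[:, None], i, js[None, :]]
                    sib = I[cg.b_v[:, None], j, js[None, :]]
                    vals = np.logaddexp.reduce(
                        (parent + cg.b_logp[:, None]) + sib, axis=1
                    )
                    np.logaddexp.at(cell, cg.b_u, vals)
                # right child V of T -> U V: parents [h, j), sibling [h, i)
                if i >= 1:
                    hs = np.arange(0, i)
                    parent = O[cg.b_t[:, None], hs[None, :], j]
                    sib = I[cg.b_u[:, None], hs[None, :], i]
                    vals = np.logaddexp.reduce(
                        (parent + cg.b_logp[:, None]) + sib, axis=1
                    )
                    np.logaddexp.at(cell, cg.b_v, vals)
            O[:, i, j] = cell
    return O


def sequence_outside(grammar: Grammar, params: ScfgParams, sequence: str):
    """Outside table (and the inside table and total, which it needs)."""
    x = _encode_sequence(sequence)
    cg = _Compiled(grammar, params)
    I = _inside_tables(cg, x, "sum")
    O = _outside_tables(cg, x, I)
    return O, I, float(I[cg.start, 0, len(x)])


def sequence_outside_posteriors(
    grammar: Grammar, params: ScfgParams, sequence: str
) -> PosteriorMatrix:
    """Posterior base-pair probabilities via inside-outside.

    p(i,j) sums, over PAIR rules T -> (U), the probability mass of derivations
    in which T spans positions i..j inclusive, normalised by the total
    likelihood.  q(i) = 1 - sum_j p(min,max).
    """
    x = _encode_sequence(sequence)
    n = len(x)
    cg = _Compiled(grammar, params)
    I = _inside_tables(cg, x, "sum")
    total = I[cg.start, 0, n] if n else _NEG_INF
    if total == _NEG_INF:
        raise ValueError("sequence not in grammar's support")
    O = _outside_tables(cg, x, I)
    P = np.zeros((n, n))
    if len(cg.p_t):
        for i in range(n):
            for j in range(i + 2, n):
                vals = (
                    O[cg.p_t, i, j + 1]
                    + (cg.p_logp + cg.emit_p[x[i], x[j]])
                    + I[cg.p_u, i + 1, j]
                )
                P[i, j] = np.exp(np.logaddexp.reduce(vals) - total)
    q = 1.0 - (P.sum(axis=0) + P.sum(axis=1))
    return PosteriorMatrix(pair_prob=P, unpaired_prob=q)


def sequence_expected_counts(grammar: Grammar, params: ScfgParams, sequence: str):
    """Expected rule and emission usage counts for one sequence (EM E-step).

    Returns ``(rule_counts, unpaired_counts, paired_counts, log_likelihood)``;
    None counts when the sequence is outside the grammar's support.
    """
    x = _encode_sequence(sequence)
    n = len(x)
    cg = _Compiled(grammar, params)
    I = _inside_tables(cg, x, "sum")
    total = I[cg.start, 0, n] if n else _NEG_INF
    if total == _NEG_INF:
        return None, None, None, _NEG_INF
    O = _outside_tables(cg, x, I)

    rule_counts = {r: 0.0 for r in grammar.rules}
    unpaired_counts = np.zeros(4)
    paired_counts = np.zeros((4, 4))
    for i in range(n):
        vals = np.exp((O[cg.u_t, i, i + 1] + (cg.u_logp + cg.emit_u[x[i]])) - total)
        for rule, v in zip(cg.u_rules, vals):
            rule_counts[rule] += float(v)
        unpaired_counts[x[i]] += float(vals.sum())
    for length in range(2, n + 1):
        for i in range(n - length + 1):
            j = i + length
            if length >= 3 and len(cg.p_t):
                vals = np.exp(
                    (
                        O[cg.p_t, i, j]
                        + (cg.p_logp + cg.emit_p[x[i], x[j - 1]])
                        + I[cg.p_u, i + 1, j - 1]
                    )
                    - total
                )
                for rule, v in zip(cg.p_rules, vals):
                    rule_counts[rule] += float(v)
                paired_counts[x[i], x[j - 1]] += float(vals.sum())
            if len(cg.b_t):
                ks = np.arange(i + 1, j)
                left = I[cg.b_u[:, None], i, ks[None, :]]
                right = I[cg.b_v[:, None], ks[None, :], j]
                scores = (
                    (O[cg.b_t, i, j][:, None] + cg.b_logp[:, None]) + left + right
                ) - total
                vals = np.exp(scores).sum(axis=1)
                for rule, v in zip(cg.b_rules, vals):
                    rule_counts[rule] += float(v)
    return rule_counts, unpaired_counts, paired_counts, float(total)


# ---------------------------------------------------------------------------
# Small utilities shared by diagnostics and sampling


def min_yield_lengths(grammar: Grammar) -> dict[str, float]:
    """Guaranteed minimal terminal yield per non-terminal (inf if unproductive)."""
    m = {nt: np.inf for nt in grammar.nonterminals}
    changed = True
    while changed:
        changed = False
        for rule in grammar.rules:
            if rule.kind is RuleKind.UNPAIRED:
                v = 1.0
            elif rule.kind is RuleKind.PAIR:
                v = 2.0 + m[rule.children[0]]
            else:
                v = m[rule.children[0]] + m[rule.children[1]]
            if v < m[rule.lhs]:
                m[rule.lhs] = v
                changed = True
    return m


def derivable_lengths(grammar: Grammar, max_len: int) -> set[int]:
    """Lengths <= max_len of strings derivable from the start symbol."""
    nts = grammar.nonterminals
    reach: dict[str, set[int]] = {nt: set() for nt in nts}
    changed = True
    while changed:
        changed = False
        for rule in grammar.rules:
            cur = reach[rule.lhs]
            if rule.kind is RuleKind.UNPAIRED:
                new = {1}
            elif rule.kind is RuleKind.PAIR:
                new = {l + 2 for l in reach[rule.children[0]] if l + 2 <= max_len}
            else:
                new = {
                    a + b
                    for a in reach[rule.children[0]]
                    for b in reach[rule.children[1]]
                    if a + b <= max_len
                }
            if not new <= cur:
                cur |= new
                changed = True
    return reach[grammar.start]
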