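"""Independent brute-force oracle: exhaustive derivation enumeration.

Implemented by naive recursive descent over substrings (no shared dynamic
program with the package), so it can serve as the reference for CYK, inside,
derivation counting, posteriors, and MEA on short inputs.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from rnascfg.grammar import Grammar, RuleKind, ScfgParams


def enumerate_derivations(grammar: Grammar, text: str) -> list[tuple]:
    """All derivation trees of a dot-bracket string from the start symbol.

    Trees are nested tuples ``(rule, child_tree, ...)``.
    """

    @lru_cache(maxsize=None)
    def derive(nt: str, s: str) -> tuple:
        results = []
        for rule in grammar.rules_for(nt):
            if rule.kind is RuleKind.UNPAIRED:
                if s == ".":
                    results.append((rule,))
            elif rule.kind is RuleKind.PAIR:
                if len(s) >= 3 and s[0] == "(" and s[-1] == ")":
                    for sub in derive(rule.children[0], s[1:-1]):
                        results.append((rule, sub))
            else:
                u, v = rule.children
                for k in range(1, len(s)):
                    lefts = derive(u, s[:k])
                    if not lefts:
                        continue
                    rights = derive(v, s[k:])
                    for lt in lefts:
                        for rt in rights:
                            results.append((rule, lt, rt))
        return tuple(results)

    if not text:
        return []
    return list(derive(grammar.start, text))


def tree_rules(tree: tuple):
    yield tree[0]
    for sub in tree[1:]:
        yield from tree_rules(sub)


def tree_probability(tree: tuple, params: ScfgParams) -> float:
    p = 1.0
    for rule in tree_rules(tree):
        p *= params.rule_prob[rule]
    return p


def all_dotbracket_strings(n: int) -> list[str]:
    """All balanced dot-bracket strings of length n (brute force over 3^n)."""
    out = []
    for chars in itertools.product("().", repeat=n):
        depth = 0
        ok = True
        for c in chars:
            if c == "(":
                depth += 1
            elif c == ")":
                depth -= 1
                if depth < 0:
                    ok = False
                    break
        if ok and depth == 0:
            out.append("".join(chars))
    return out


def structure_pairs(text: str) -> frozenset[tuple[int, int]]:
    stack, pairs = [], set()
    for pos, c in enumerate(text):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            pairs.add((stack.pop(), pos))
    return frozenset(pairs)


def emission_probability(structure_text: str, sequence: str, params: ScfgParams) -> float:
    pairs = structure_pairs(structure_text)
    paired = {p for ij in pairs for p in ij}
    prob = 1.0
    for i, j in pairs:
        prob *= params.paired_emit[(sequence[i], sequence[j])]
    for i, base in enumerate(sequence):
        if i not in paired:
            prob *= params.unpaired_emit[base]
    return prob


def sequence_enumeration(grammar: Grammar, params: ScfgParams, sequence: str):
    """Every (structure, derivation, joint probability) for a sequence.

    The joint probability is P(derivation) x P(sequence | structure).
    """
    entries = []
    for text in all_dotbracket_strings(len(sequence)):
        emis = emission_probability(text, sequence, params)
        for tree in enumerate_derivations(grammar, text):
            entries.append((text, tree, tree_probability(tree, params) * emis))
    return entries


def oracle_posteriors(grammar: Grammar, params: ScfgParams, sequence: str) -> np.ndarray:
    n = len(sequence)
    entries = sequence_enumeration(grammar, params, sequence)
    total = sum(p for _, _, p in entries)
    P = np.zeros((n, n))
    for text, _, p in entries:
        for i, j in structure_pairs(text):
            P[i, j] += p
    return P / total


def random_structure_text(rng: np.random.Generator, length: int) -> str:
    if length <= 0:
        return ""
    if length >= 2 and rng.random() < 0.4:
        inner = random_structure_text(rng, length - 2)
        split = int(rng.integers(0, len(inner) + 1))
        return "(" + inner[:split] + ")" + inner[split:]
    return "." + random_structure_text(rng, length - 1)


def oracle_mea(P: np.ndarray, q: np.ndarray, gamma: float):
    """Best non-crossing structure by exhaustive scoring (small n)."""
    n = len(q)
    best_val, best_text = -np.inf, None
    for text in all_dotbracket_strings(n):
        pairs = structure_pairs(text)
        paired = {p for ij in pairs for p in ij}
        val = sum(gamma * P[i, j] for i, j in pairs)
        val += sum(q[i] for i in range(n) if i not in paired)
        if val > best_val + 1e-12:
            best_val, best_text = val, text
    return best_val, best_text
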