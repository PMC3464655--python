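"""Synthetic (sequence, structure) data sampled from an SCFG with known
parameters.

A structure is produced by a leftmost stochastic derivation from the start
symbol; nucleotides are then allocated per site, unpaired positions from the
4-way table and paired positions jointly from the 16-way table.  Derivations
whose guaranteed minimal yield exceeds ``max_len`` are rejected and retried
(rejection keeps the conditional distribution over accepted structures
correct, rather than renormalising rule probabilities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grammar import (
    BASE_PAIRS,
    BASES,
    Grammar,
    RuleKind,
    ScfgParams,
    builtin_grammar,
)
from .parse import min_yield_lengths
from .structure import StructuredSequence, parse_dotbracket

__all__ = ["SamplerConfig", "sample_structure", "sample_records", "default_fixture"]


@dataclass
class SamplerConfig:
    grammar: Grammar
    params: ScfgParams
    n_records: int
    max_len: int
    seed: int
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.max_len < 1 or self.n_records < 1:
            raise ValueError("max_len and n_records must be >= 1")


def default_fixture() -> tuple[Grammar, ScfgParams]:
    """The bundled KH99p grammar with hand-set synthetic sampling parameters."""
    return builtin_grammar("KH99p_synthetic", with_params=True)


def sample_structure(
    grammar: Grammar,
    params: ScfgParams,
    rng: np.random.Generator,
    max_len: int,
) -> str | None:
    """One leftmost stochastic derivation; None when rejected for length.

    The derivation aborts as soon as the sentential form's guaranteed minimal
    terminal yield exceeds ``max_len`` (returned strings are always derivable,
    but a rejection does not imply no short derivation existed).
    """
    min_len = min_yield_lengths(grammar)
    if not np.isfinite(min_len[grammar.start]):
        raise ValueError("start symbol derives no terminal string")
    by_nt: dict[str, tuple[list, np.ndarray]] = {}
    for nt in grammar.nonterminals:
        rules = grammar.rules_for(nt)
        if rules:
            probs = np.asarray([params.rule_prob[r] for r in rules])
            by_nt[nt] = (list(rules), probs / probs.sum())

    form: list[str] = [grammar.start]  # symbols; terminals are '(', ')', '.'
    guaranteed = min_len[grammar.start]
    max_steps = 50 * max_len + 1000
    for _ in range(max_steps):
        idx = next((k for k, s in enumerate(form) if s in min_len), None)
        if idx is None:
            return "".join(form)
        nt = form[idx]
        if nt not in by_nt:
            raise ValueError(f"non-terminal {nt} has no rules")
        rules, probs = by_nt[nt]
        rule = rules[int(rng.choice(len(rules), p=probs))]
        if rule.kind is RuleKind.UNPAIRED:
            repl = ["."]
            guaranteed += 1.0 - min_len[nt]
        elif rule.kind is RuleKind.PAIR:
            u = rule.children[0]
            repl = ["(", u, ")"]
            guaranteed += 2.0 + min_len[u] - min_len[nt]
        else:
            u, v = rule.children
            repl = [u, v]
            guaranteed += min_len[u] + min_len[v] - min_len[nt]
        form[idx : idx + 1] = repl
        if guaranteed > max_len:
            return None
    return None  # runaway derivation; treat as rejected


def _sample_sequence(
    structure_text: str, params: ScfgParams, rng: np.random.Generator
) -> str:
    structure = parse_dotbracket(structure_text)
    up = np.asarray([params.unpaired_emit[b] for b in BASES])
    up = up / up.sum()
    pp = np.asarray([params.paired_emit[bp] for bp in BASE_PAIRS])
    pp = pp / pp.sum()
    chars = [""] * structure.length
    paired = structure.paired_positions
    for i, j in sorted(structure.pairs):
        a, b = BASE_PAIRS[int(rng.choice(16, p=pp))]
        chars[i], chars[j] = a, b
    for i in range(structure.length):
        if i not in paired:
            chars[i] = BASES[int(rng.choice(4, p=up))]
    return "".join(chars)


def sample_records(config: SamplerConfig) -> list[StructuredSequence]:
    """Sample ``n_records`` structured sequences; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    records: list[StructuredSequence] = []
    for k in range(config.n_records):
        text = None
        for _ in range(config.max_attempts):
            text = sample_structure(config.grammar, config.params, rng, config.max_len)
            if text is not None:
                break
        if text is None:
            raise RuntimeError(
                f"could not sample a structure of length <= {config.max_len} in "
                f"{config.max_attempts} attempts; increase max_len"
            )
        seq = _sample_sequence(text, config.params, rng)
        records.append(
            StructuredSequence(f"synth{k:04d}", seq, parse_dotbracket(text))
        )
    return records
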