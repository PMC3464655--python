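"""Parameter estimation for stochastic grammars.

Two routes to an :class:`~rnascfg.grammar.ScfgParams`:

* **Supervised counting** from (sequence, trusted structure) pairs.  Each
  structure is parsed once; for unambiguous grammars the derivation is unique,
  for ambiguous grammars one derivation is drawn uniformly at random (the
  usage counts are then multinomial sufficient statistics).  Emission counts
  come from the trusted structures' paired/unpaired status.
* **Expectation-maximisation** (inside-outside) on the sequences alone; the
  trusted structures are ignored.  Each iteration computes expected rule and
  emission counts under the current parameters and renormalises; the
  log-likelihood trace is non-decreasing up to floating-point slack.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grammar import BASES, Grammar, ProductionRule, ScfgParams
from .parse import sample_derivation, sequence_expected_counts
from .structure import StructuredSequence, to_dotbracket

__all__ = ["CountTable", "params_from_counts", "supervised_train", "em_train"]

logger = logging.getLogger(__name__)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class CountTable:
    """Rule usage counts plus 4-way unpaired and 16-way paired emission counts."""

    rule_counts: dict[ProductionRule, float]
    unpaired_counts: np.ndarray = field(default_factory=lambda: np.zeros(4))
    paired_counts: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))

    @classmethod
    def zeros(cls, grammar: Grammar) -> "CountTable":
        return cls(rule_counts={r: 0.0 for r in grammar.rules})

    def add_derivation(self, rule_multiset: dict[ProductionRule, int]) -> None:
        for rule, c in rule_multiset.items():
            self.rule_counts[rule] = self.rule_counts.get(rule, 0.0) + c

    def add_emissions(self, record: StructuredSequence) -> None:
        paired = record.structure.paired_positions
        for i, j in record.structure.pairs:
            self.paired_counts[_BASE_INDEX[record.sequence[i]],
                               _BASE_INDEX[record.sequence[j]]] += 1.0
        for i, base in enumerate(record.sequence):
            if i not in paired:
                self.unpaired_counts[_BASE_INDEX[base]] += 1.0


def params_from_counts(
    grammar: Grammar, counts: CountTable, pseudocount: float = 0.0
) -> ScfgParams:
    """Multinomial maximum-likelihood (or MAP with pseudocounts) parameters.

    Each non-terminal's rule counts and each emission table are normalised
    independently after adding ``pseudocount`` to every entry.  A non-terminal
    whose rules have zero total count (and zero pseudocount) falls back to the
    uniform distribution over its rules, with a logged notice.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    rule_prob: dict[ProductionRule, float] = {}
    for nt in grammar.nonterminals:
        rules = grammar.rules_for(nt)
        if not rules:
            continue
        raw = np.asarray(
            [counts.rule_counts.get(r, 0.0) + pseudocount for r in rules]
        )
        total = raw.sum()
        if total <= 0.0:
            logger.info("non-terminal %s unused; assigning uniform rule probabilities", nt)
            raw = np.ones(len(rules))
            total = float(len(rules))
        for r, c in zip(rules, raw):
            rule_prob[r] = float(c / total)

    def _norm(table: np.ndarray) -> np.ndarray:
        t = table + pseudocount
        s = t.sum()
        if s <= 0.0:
            return np.full_like(t, 1.0 / t.size)
        return t / s

    up = _norm(counts.unpaired_counts)
    pp = _norm(counts.paired_counts)
    return ScfgParams(
        rule_prob=rule_prob,
        unpaired_emit={b: float(up[i]) for i, b in enumerate(BASES)},
        paired_emit={(a, b): float(pp[i, j])
                     for i, a in enumerate(BASES) for j, b in enumerate(BASES)},
    )


def supervised_train(
    grammar: Grammar,
    records: Sequence[StructuredSequence],
    pseudocount: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ScfgParams:
    """Estimate parameters from trusted structures by derivation counting.

    Records whose structure the grammar cannot derive are skipped (count
    logged); raises if no record is derivable.  For ambiguous grammars one
    derivation per record is drawn uniformly (seeded via ``rng``); for
    unambiguous grammars no randomness is consumed.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0)
    counts = CountTable.zeros(grammar)
    skipped = 0
    for record in records:
        text = to_dotbracket(record.structure)
        try:
            deriv = sample_derivation(grammar, text, rng)
        except ValueError:
            skipped += 1
            continue
        counts.add_derivation(deriv.rule_multiset())
        counts.add_emissions(record)
    if skipped:
        logger.info("supervised_train: skipped %d/%d underivable records",
                    skipped, len(records))
    if skipped == len(records):
        raise ValueError("no training structure is derivable by the grammar")
    return params_from_counts(grammar, counts, pseudocount)


def em_train(
    grammar: Grammar,
    records: Sequence[StructuredSequence],
    init: ScfgParams | str = "uniform",
    max_iters: int = 100,
    tol: float = 1e-4,
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
) -> tuple[ScfgParams, list[float]]:
    """Inside-outside (EM) training on sequences alone.

    ``init`` is "uniform" or explicit parameters; ``jitter`` applies a seeded
    multiplicative perturbation (e.g. 0.01 for ±1%) to the uniform start to
    break symmetry.  Sequences outside the grammar's support at initialisation
    are excluded with a warning; raises if none remain.  Returns the trained
    parameters and the per-iteration log-likelihood trace (non-decreasing
    within floating-point slack).
    """
    if not records:
        raise ValueError("em_train requires at least one record")
    if isinstance(init, str):
        if init != "uniform":
            raise ValueError(f"unknown init {init!r}")
        params = ScfgParams.uniform(grammar)
        if jitter > 0.0:
            if rng is None:
                rng = np.random.default_rng(0)
            params = _jitter_params(grammar, params, jitter, rng)
    else:
        params = init

    sequences = [r.sequence for r in records]
    trace: list[float] = []
    included = [True] * len(sequences)
    prev_ll: float | None = None
    for iteration in range(max_iters):
        counts = CountTable.zeros(grammar)
        ll = 0.0
        n_used = 0
        for idx, seq in enumerate(sequences):
            if not included[idx]:
                continue
            rc, uc, pc, seq_ll = sequence_expected_counts(grammar, params, seq)
            if rc is None:
                included[idx] = False
                logger.warning("em_train: sequence %d outside grammar support; excluded", idx)
                continue
            for r, c in rc.items():
                counts.rule_counts[r] += c
            counts.unpaired_counts += uc
            counts.paired_counts += pc
            ll += seq_ll
            n_used += 1
        if n_used == 0:
            raise ValueError("all sequences are outside the grammar's support")
        trace.append(ll)
        params = params_from_counts(grammar, counts, pseudocount=0.0)
        if prev_ll is not None and ll - prev_ll < tol:
            break
        prev_ll = ll
    return params, trace


def _jitter_params(
    grammar: Grammar, params: ScfgParams, jitter: float, rng: np.random.Generator
) -> ScfgParams:
    rule_prob = dict(params.rule_prob)
    for nt in grammar.nonterminals:
        rules = grammar.rules_for(nt)
        if not rules:
            continue
        vals = np.asarray([rule_prob[r] for r in rules])
        vals = vals * (1.0 + jitter * rng.uniform(-1.0, 1.0, size=len(vals)))
        vals /= vals.sum()
        for r, v in zip(rules, vals):
            rule_prob[r] = float(v)
    return ScfgParams(rule_prob, dict(params.unpaired_emit), dict(params.paired_emit))
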