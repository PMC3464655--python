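"""Search over grammar space: an evolutionary algorithm, exhaustive
enumeration of two-non-terminal grammars, and local add/delete search.

The evolutionary algorithm keeps a population of grammars, grows it each
generation with mutated or bred offspring, evaluates fitness by training the
grammar on a set of trusted structures and scoring its predictions (lower
fitness is better), and pares the population back by stochastic elimination
with probability increasing in fitness.  The rule ``B -> .`` is kept constant
throughout, anchoring a guaranteed unpaired emitter.

Five mutation operators are available: change the start symbol; add or delete
a production rule; introduce a new non-terminal (with rules making it
reachable and productive of rules); duplicate an existing non-terminal's rule
set under a new name; rewire one child of a branch or pair rule.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .decode import predict_cyk, predict_mea
from .grammar import (
    Grammar,
    ProductionRule,
    RuleKind,
    addable_rules,
    all_normal_form_rules,
    branch,
    pair,
    unpaired,
    validate_normal_form,
)
from .metrics import MetricReport, aggregate, mountain_distance
from .parse import min_yield_lengths
from .structure import StructuredSequence
from .train import em_train, supervised_train

__all__ = [
    "EvolutionConfig",
    "SearchState",
    "initial_population",
    "mutate",
    "breed",
    "evaluate_fitness",
    "select",
    "run_evolution",
    "enumerate_two_nonterminal_grammars",
    "brute_force_space",
    "local_search_grammars",
    "local_search",
    "DEFAULT_MUTATION_WEIGHTS",
    "WORST_FITNESS",
]

WORST_FITNESS = math.inf
PROTECTED_RULE = unpaired("B")

# (start change, add/delete rule, new non-terminal, duplicate, rewire);
# the add/delete type splits 4:1 toward addition.
DEFAULT_MUTATION_WEIGHTS = (0.05, 0.50, 0.15, 0.10, 0.20)

FITNESS_CHOICES = ("mountain", "sensitivity", "ppv", "fscore", "composite")


@dataclass
class EvolutionConfig:
    generations: int = 30
    population_size: int = 16
    offspring_per_generation: int = 8
    mutation_weights: tuple[float, ...] = DEFAULT_MUTATION_WEIGHTS
    breed_fraction: float = 0.25
    fitness: str = "mountain"
    composite_terms: dict[str, float] = field(default_factory=dict)
    training_method: str = "cyk"  # "cyk" | "io"
    prediction_method: str = "cyk"  # "cyk" | "mea"
    gamma: float = 2.0
    em_max_iters: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if len(self.mutation_weights) != 5 or any(w < 0 for w in self.mutation_weights):
            raise ValueError("mutation_weights must be 5 nonnegative reals")
        if not any(self.mutation_weights):
            raise ValueError("mutation_weights must not all be zero")
        if self.fitness not in FITNESS_CHOICES:
            raise ValueError(f"fitness must be one of {FITNESS_CHOICES}")
        if not 0.0 <= self.breed_fraction <= 1.0:
            raise ValueError("breed_fraction must be in [0, 1]")


@dataclass
class SearchState:
    population: list[tuple[Grammar, float]]
    champion: tuple[Grammar, float]
    history: list[tuple[float, float]]  # (mean fitness, champion fitness)
    champion_test_report: MetricReport | None = None
    all_grammars: list[Grammar] | None = None  # every grammar ever evaluated


# ---------------------------------------------------------------------------
# Population construction


def initial_population() -> list[Grammar]:
    """The sixteen seed grammars: S -> SS|SB|BS|BB|(S)|. , B -> . , with
    every subset of the four branch rules excluded."""
    branches = [branch("S", a, b) for a, b in
                (("S", "S"), ("S", "B"), ("B", "S"), ("B", "B"))]
    fixed = (pair("S", "S"), unpaired("S"), PROTECTED_RULE)
    population = []
    for mask in range(16):
        kept = tuple(r for bit, r in enumerate(branches) if not mask & (1 << bit))
        population.append(Grammar(("S", "B"), "S", kept + fixed))
    return population


def _fresh_symbol(used: set[str]) -> str:
    for ch in "ABCDEFGHIJKLMNOPQRSTUVWXYZ":
        if ch not in used:
            return ch
    k = 1
    while f"N{k}" in used:
        k += 1
    return f"N{k}"


def _reachable(grammar: Grammar) -> set[str]:
    seen = {grammar.start}
    frontier = [grammar.start]
    while frontier:
        nt = frontier.pop()
        for rule in grammar.rules_for(nt):
            for child in rule.children:
                if child not in seen:
                    seen.add(child)
                    frontier.append(child)
    return seen


def mutate(
    grammar: Grammar,
    rng: np.random.Generator,
    weights: Sequence[float] = DEFAULT_MUTATION_WEIGHTS,
) -> Grammar:
    """Apply one stochastic mutation; the result is valid normal form and
    retains the protected rule B -> . .  Inapplicable mutation types are
    resampled; raises only if no type applies."""
    if PROTECTED_RULE not in grammar.rules:
        raise ValueError("grammar must contain the protected rule B -> .")
    weights = np.asarray(weights, dtype=float)
    remaining = list(range(5))
    while remaining:
        w = weights[remaining]
        if w.sum() == 0:
            w = np.ones(len(remaining))
        mtype = remaining[int(rng.choice(len(remaining), p=w / w.sum()))]
        result = _MUTATIONS[mtype](grammar, rng)
        if result is not None:
            return result
        remaining.remove(mtype)
    raise ValueError("no mutation type is applicable to this grammar")


def _mutate_start(grammar: Grammar, rng) -> Grammar | None:
    others = [nt for nt in grammar.nonterminals
              if nt != grammar.start and grammar.rules_for(nt)]
    if not others:
        return None
    new_start = others[int(rng.integers(len(others)))]
    return Grammar(grammar.nonterminals, new_start, grammar.rules)


def _mutate_add_delete(grammar: Grammar, rng) -> Grammar | None:
    add = rng.random() < 0.8  # 4:1 toward addition
    for do_add in (add, not add):
        if do_add:
            candidates = sorted(addable_rules(grammar))
            if candidates:
                rule = candidates[int(rng.integers(len(candidates)))]
                return grammar.add_rule(rule)
        else:
            deletable = [
                r for r in grammar.rules
                if r != PROTECTED_RULE and len(grammar.rules_for(r.lhs)) > 1
            ]
            if deletable:
                rule = deletable[int(rng.integers(len(deletable)))]
                return grammar.remove_rule(rule)
    return None


def _mutate_new_nonterminal(grammar: Grammar, rng) -> Grammar | None:
    used = set(grammar.nonterminals)
    fresh = _fresh_symbol(used)
    hosts = sorted(_reachable(grammar))
    host = hosts[int(rng.integers(len(hosts)))]
    link_kind = int(rng.integers(3))
    if link_kind == 0:
        link = pair(host, fresh)
    else:
        partner = grammar.nonterminals[int(rng.integers(len(grammar.nonterminals)))]
        link = branch(host, fresh, partner) if link_kind == 1 else branch(host, partner, fresh)
    all_nts = grammar.nonterminals + (fresh,)
    own_kind = int(rng.integers(3))
    if own_kind == 0:
        own = unpaired(fresh)
    elif own_kind == 1:
        own = pair(fresh, all_nts[int(rng.integers(len(all_nts)))])
    else:
        own = branch(fresh,
                     all_nts[int(rng.integers(len(all_nts)))],
                     all_nts[int(rng.integers(len(all_nts)))])
    return Grammar(all_nts, grammar.start, grammar.rules + (link, own))


def _mutate_duplicate(grammar: Grammar, rng) -> Grammar | None:
    sources = [nt for nt in grammar.nonterminals if grammar.rules_for(nt)]
    if not sources:
        return None
    source = sources[int(rng.integers(len(sources)))]
    fresh = _fresh_symbol(set(grammar.nonterminals))
    copies = tuple(
        ProductionRule(fresh, r.kind, r.children) for r in grammar.rules_for(source)
    )
    return Grammar(grammar.nonterminals + (fresh,), grammar.start,
                   grammar.rules + copies)


def _mutate_rewire(grammar: Grammar, rng) -> Grammar | None:
    targets = [r for r in grammar.rules
               if r.kind in (RuleKind.BRANCH, RuleKind.PAIR)]
    if not targets:
        return None
    existing = set(grammar.rules)
    order = rng.permutation(len(targets))
    for t_idx in order:
        rule = targets[int(t_idx)]
        candidates = []
        if rule.kind is RuleKind.PAIR:
            for nt in grammar.nonterminals:
                alt = pair(rule.lhs, nt)
                if alt != rule and alt not in existing:
                    candidates.append(alt)
        else:
            u, v = rule.children
            for nt in grammar.nonterminals:
                for alt in (branch(rule.lhs, nt, v), branch(rule.lhs, u, nt)):
                    if alt != rule and alt not in existing:
                        candidates.append(alt)
            for nt, nt2 in itertools.product(grammar.nonterminals, repeat=2):
                alt = branch(rule.lhs, nt, nt2)
                if alt != rule and alt not in existing:
                    candidates.append(alt)
        if candidates:
            # dedupe, keep deterministic order
            seen: set[ProductionRule] = set()
            uniq = [c for c in candidates if not (c in seen or seen.add(c))]
            alt = uniq[int(rng.integers(len(uniq)))]
            return grammar.with_rules(
                tuple(alt if r == rule else r for r in grammar.rules)
            )
    return None


_MUTATIONS = (
    _mutate_start,
    _mutate_add_delete,
    _mutate_new_nonterminal,
    _mutate_duplicate,
    _mutate_rewire,
)


def breed(g1: Grammar, g2: Grammar) -> Grammar:
    """Combine two grammars into one deriving every string either parent can.

    The child has a new start symbol S whose rules are the union of both
    parents' start rules; each parent's non-terminals (except the shared B)
    are renamed apart, with references to the parent's start symbol redirected
    to S.
    """
    used = {"S", "B"}
    renames: list[dict[str, str]] = []
    for g in (g1, g2):
        mapping = {}
        for nt in g.nonterminals:
            if nt == "B":
                mapping[nt] = "B"
            else:
                name = _fresh_symbol(used)
                used.add(name)
                mapping[nt] = name
        renames.append(mapping)

    def _map_symbol(sym: str, g: Grammar, mapping: dict[str, str]) -> str:
        if sym == g.start:
            return "S"
        return mapping[sym]

    rules: list[ProductionRule] = []

    def _add(rule: ProductionRule) -> None:
        if rule not in rules:
            rules.append(rule)

    for g, mapping in zip((g1, g2), renames):
        for rule in g.rules_for(g.start):
            children = tuple(_map_symbol(c, g, mapping) for c in rule.children)
            _add(ProductionRule("S", rule.kind, children))
    for g, mapping in zip((g1, g2), renames):
        for rule in g.rules:
            children = tuple(_map_symbol(c, g, mapping) for c in rule.children)
            _add(ProductionRule(mapping[rule.lhs], rule.kind, children))

    nts = ["S"]
    for g, mapping in zip((g1, g2), renames):
        for nt in g.nonterminals:
            name = mapping[nt]
            if name not in nts and name != "B":
                nts.append(name)
    nts.append("B")
    if PROTECTED_RULE not in rules:
        rules.append(PROTECTED_RULE)
    return Grammar(tuple(nts), "S", tuple(rules))


# ---------------------------------------------------------------------------
# Fitness and selection


def _train(grammar, records, config, rng):
    if config.training_method == "io":
        params, _ = em_train(grammar, records, max_iters=config.em_max_iters, rng=rng)
        return params
    return supervised_train(grammar, records, rng=rng)


def _predict(grammar, params, record, config):
    if config.prediction_method == "mea":
        return predict_mea(grammar, params, record.sequence, config.gamma)
    return predict_cyk(grammar, params, record.sequence)


def evaluate_fitness(
    grammar: Grammar,
    train_records: Sequence[StructuredSequence],
    config: EvolutionConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Train on the records, predict them back, and score (lower = better).

    Metric fitnesses (sensitivity/PPV/F-score) are negated; the mountain
    fitness is the summed mountain-metric distance.  The composite fitness is
    the negated F-score plus optional terms: ``failure_penalty`` per failed
    prediction, ``complexity_cost`` per production rule, and a reward
    ``longest_correct`` times the longest exactly-predicted record length.
    Grammars that parse no training structure get the worst-possible sentinel.
    """
    if not train_records:
        raise ValueError("fitness evaluation needs non-empty records")
    if rng is None:
        rng = np.random.default_rng(0)
    try:
        params = _train(grammar, train_records, config, rng)
    except ValueError:
        return WORST_FITNESS
    preds = [_predict(grammar, params, rec, config) for rec in train_records]
    n_failed = sum(p.failed for p in preds)
    if config.fitness == "mountain":
        fitness = sum(
            mountain_distance(p.structure, rec.structure)
            for p, rec in zip(preds, train_records)
        )
    elif config.fitness in ("sensitivity", "ppv", "fscore"):
        report = aggregate(train_records, preds)
        fitness = -getattr(report, config.fitness)
    else:  # composite
        report = aggregate(train_records, preds)
        terms = config.composite_terms
        fitness = -report.fscore
        fitness += terms.get("failure_penalty", 0.0) * n_failed
        fitness += terms.get("complexity_cost", 0.0) * len(grammar.rules)
        longest = 0
        for p, rec in zip(preds, train_records):
            if p.structure == rec.structure:
                longest = max(longest, rec.structure.length)
        fitness -= terms.get("longest_correct", 0.0) * longest
    return float(fitness)


def select(
    population_with_fitness: Sequence[tuple[Grammar, float]],
    target_size: int,
    rng: np.random.Generator,
) -> list[tuple[Grammar, float]]:
    """Stochastic elimination down to ``target_size``.

    One grammar is eliminated at a time with probability proportional to
    ``fitness - best_fitness + eps`` (lower fitness is better); sentinel-worst
    grammars are eliminated first.  The single best grammar is never
    eliminated (elitism of size 1).
    """
    pool = list(population_with_fitness)
    if len(pool) < target_size:
        raise ValueError("population smaller than target size")
    eps = 1e-6
    while len(pool) > target_size:
        fitnesses = [f for _, f in pool]
        best_idx = min(range(len(pool)), key=lambda k: fitnesses[k])
        candidates = [k for k in range(len(pool)) if k != best_idx]
        infinite = [k for k in candidates if not math.isfinite(fitnesses[k])]
        if infinite:
            victim = infinite[int(rng.integers(len(infinite)))]
        else:
            best_f = fitnesses[best_idx]
            weights = np.asarray([fitnesses[k] - best_f + eps for k in candidates])
            victim = candidates[int(rng.choice(len(candidates), p=weights / weights.sum()))]
        pool.pop(victim)
    return pool


def run_evolution(
    train_records: Sequence[StructuredSequence],
    test_records: Sequence[StructuredSequence] | None,
    config: EvolutionConfig,
    collect_all: bool = False,
) -> SearchState:
    """Run the evolutionary search; fully reproducible for a fixed seed.

    Fitness evaluations are cached by grammar identity within the run.  The
    champion is the best grammar ever evaluated; its fitness trace is
    non-increasing by construction.  If ``test_records`` is given, the
    champion is re-trained and scored on them for the final report.
    """
    if config.generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(config.seed)
    cache: dict[tuple, float] = {}
    all_grammars: list[Grammar] | None = [] if collect_all else None

    def fitness_of(g: Grammar) -> float:
        if all_grammars is not None:
            all_grammars.append(g)
        key = g.canonical_key()
        if key not in cache:
            cache[key] = evaluate_fitness(g, train_records, config, rng)
        return cache[key]

    population = [(g, fitness_of(g)) for g in initial_population()]
    population = select(population, min(config.population_size, len(population)), rng)
    champion = min(population, key=lambda gf: gf[1])
    history: list[tuple[float, float]] = []

    for _ in range(config.generations):
        offspring: list[tuple[Grammar, float]] = []
        for _ in range(config.offspring_per_generation):
            if len(population) >= 2 and rng.random() < config.breed_fraction:
                i, j = rng.choice(len(population), size=2, replace=False)
                child = breed(population[int(i)][0], population[int(j)][0])
            else:
                parent = population[int(rng.integers(len(population)))][0]
                child = mutate(parent, rng, config.mutation_weights)
            offspring.append((child, fitness_of(child)))
        population = select(population + offspring, config.population_size, rng)
        gen_best = min(population + [champion], key=lambda gf: gf[1])
        if gen_best[1] < champion[1]:
            champion = gen_best
        finite = [f for _, f in population if math.isfinite(f)]
        mean_f = float(np.mean(finite)) if finite else math.inf
        history.append((mean_f, champion[1]))

    state = SearchState(population=population, champion=champion, history=history,
                        all_grammars=all_grammars)
    if test_records:
        try:
            params = _train(champion[0], train_records, config,
                            np.random.default_rng(config.seed))
            preds = [_predict(champion[0], params, rec, config) for rec in test_records]
            state.champion_test_report = aggregate(test_records, preds)
        except ValueError:
            state.champion_test_report = None
    return state


# ---------------------------------------------------------------------------
# Brute force and local search


def enumerate_two_nonterminal_grammars(
    nonterminals: tuple[str, str] = ("S", "U"),
) -> Iterator[Grammar]:
    """All 2^14 grammars over two non-terminals (every subset of the 14
    normal-form rules), each carrying the fixed extra symbol B with B -> . ."""
    universe = all_normal_form_rules(nonterminals)
    assert len(universe) == 14
    nts = nonterminals + ("B",)
    for mask in range(1 << 14):
        rules = tuple(r for bit, r in enumerate(universe) if mask & (1 << bit))
        yield Grammar(nts, nonterminals[0], rules + (PROTECTED_RULE,))


def _train_and_report(
    grammar: Grammar,
    train_records: Sequence[StructuredSequence],
    test_records: Sequence[StructuredSequence],
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> MetricReport:
    try:
        params = _train(grammar, train_records, config, rng)
    except ValueError:
        return aggregate(test_records, [_all_dots(r) for r in test_records])
    preds = [_predict(grammar, params, rec, config) for rec in test_records]
    return aggregate(test_records, preds)


def _all_dots(record: StructuredSequence):
    from .structure import Structure

    return Structure(length=len(record.sequence))


def brute_force_space(
    train_records: Sequence[StructuredSequence],
    test_records: Sequence[StructuredSequence],
    budget: int | None = None,
    config: EvolutionConfig | None = None,
) -> list[tuple[Grammar, MetricReport]]:
    """Train and evaluate every two-non-terminal grammar (optionally capped).

    Grammars whose start symbol derives no string at all are assigned zero
    metrics without training.  The result is sorted by sensitivity, best
    first (stable, so enumeration order breaks ties).
    """
    if config is None:
        config = EvolutionConfig()
    rng = np.random.default_rng(config.seed)
    results: list[tuple[Grammar, MetricReport]] = []
    for idx, grammar in enumerate(enumerate_two_nonterminal_grammars()):
        if budget is not None and idx >= budget:
            break
        if not math.isfinite(min_yield_lengths(grammar)[grammar.start]):
            report = aggregate(test_records, [_all_dots(r) for r in test_records])
        else:
            report = _train_and_report(grammar, train_records, test_records, config, rng)
        results.append((grammar, report))
    results.sort(key=lambda gr: -gr[1].sensitivity)
    return results


def local_search_grammars(grammar: Grammar, depth: str) -> list[Grammar]:
    """Neighbourhood grammars: 'add1' (one rule added), 'add2' (an unordered
    pair of distinct rules added), or 'del1' (one rule deleted; B -> . is
    protected)."""
    violations = validate_normal_form(grammar)
    if violations:
        raise ValueError("invalid grammar: " + "; ".join(violations))
    addable = sorted(addable_rules(grammar))
    if depth == "add1":
        return [grammar.add_rule(r) for r in addable]
    if depth == "add2":
        return [
            grammar.add_rule(r1).add_rule(r2)
            for r1, r2 in itertools.combinations(addable, 2)
        ]
    if depth == "del1":
        deletable = [r for r in grammar.rules if r != PROTECTED_RULE]
        return [grammar.remove_rule(r) for r in deletable]
    raise ValueError(f"unknown depth {depth!r}; use add1, add2, or del1")


def local_search(
    grammar: Grammar,
    depth: str,
    train_records: Sequence[StructuredSequence],
    test_records: Sequence[StructuredSequence],
    config: EvolutionConfig | None = None,
) -> list[tuple[Grammar, MetricReport]]:
    """Train and evaluate every neighbourhood grammar of ``grammar``."""
    if config is None:
        config = EvolutionConfig()
    rng = np.random.default_rng(config.seed)
    return [
        (g, _train_and_report(g, train_records, test_records, config, rng))
        for g in local_search_grammars(grammar, depth)
    ]
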