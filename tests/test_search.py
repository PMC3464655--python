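import itertools
import math

import numpy as np
import pytest

from rnascfg.grammar import (
    Grammar,
    RuleKind,
    branch,
    pair,
    unpaired,
    validate_normal_form,
)
from rnascfg.parse import count_derivations
from rnascfg.search import (
    DEFAULT_MUTATION_WEIGHTS,
    PROTECTED_RULE,
    EvolutionConfig,
    breed,
    brute_force_space,
    enumerate_two_nonterminal_grammars,
    evaluate_fitness,
    initial_population,
    local_search,
    local_search_grammars,
    mutate,
    run_evolution,
    select,
)
from rnascfg.sample import sample_structure
from rnascfg.grammar import ScfgParams
from rnascfg.structure import StructuredSequence, parse_dotbracket


class TestInitialPopulation:
    def test_sixteen_distinct_valid_grammars(self):
        pop = initial_population()
        assert len(pop) == 16
        assert len({g.canonical_key() for g in pop}) == 16
        for g in pop:
            assert validate_normal_form(g) == []

    def test_template_rules_always_present(self):
        for g in initial_population():
            assert pair("S", "S") in g.rules
            assert unpaired("S") in g.rules
            assert PROTECTED_RULE in g.rules

    def test_exactly_one_branchless_member(self):
        pop = initial_population()
        branchless = [
            g for g in pop
            if not any(r.kind is RuleKind.BRANCH for r in g.rules)
        ]
        assert len(branchless) == 1


class TestMutation:
    def test_duplicate_nonterminal(self, kh99p, rng):
        out = mutate(kh99p, rng, weights=(0, 0, 0, 1, 0))
        assert len(out.nonterminals) == 4
        fresh = next(nt for nt in out.nonterminals if nt not in kh99p.nonterminals)
        copied = {(r.kind, r.children) for r in out.rules_for(fresh)}
        originals = {
            nt: {(r.kind, r.children) for r in kh99p.rules_for(nt)}
            for nt in kh99p.nonterminals
        }
        assert copied in originals.values()

    def test_add_rule_only(self, kh99p, rng):
        from rnascfg.grammar import addable_rules

        out = mutate(kh99p, rng, weights=(0, 1, 0, 0, 0))
        delta = set(out.rules) ^ set(kh99p.rules)
        if len(out.rules) == len(kh99p.rules) + 1:
            (new_rule,) = delta
            assert new_rule in addable_rules(kh99p)
        else:  # the 1-in-5 deletion branch
            assert len(out.rules) == len(kh99p.rules) - 1

    def test_property_sweep_validity_and_protected_rule(self, kh99p):
        rng = np.random.default_rng(0)
        # 200 independent single mutations
        for _ in range(200):
            g = mutate(kh99p, rng, DEFAULT_MUTATION_WEIGHTS)
            assert validate_normal_form(g) == []
            assert PROTECTED_RULE in g.rules
        # plus a 50-step chain, letting the grammar grow
        g = kh99p
        for _ in range(50):
            g = mutate(g, rng, DEFAULT_MUTATION_WEIGHTS)
            assert validate_normal_form(g) == []
            assert PROTECTED_RULE in g.rules

    def test_new_nonterminal_reachable(self, kh99p):
        rng = np.random.default_rng(4)
        out = mutate(kh99p, rng, weights=(0, 0, 1, 0, 0))
        fresh = next(nt for nt in out.nonterminals if nt not in kh99p.nonterminals)
        assert out.rules_for(fresh)
        from rnascfg.search import _reachable

        assert fresh in _reachable(out)

    def test_missing_protected_rule_rejected(self, rng):
        g = Grammar(("S",), "S", (unpaired("S"),))
        with pytest.raises(ValueError):
            mutate(g, rng)


class TestBreeding:
    def test_documented_construction(self):
        g1 = Grammar(("S1", "B"), "S1",
                     (pair("S1", "S1"), unpaired("S1"), unpaired("B")))
        g2 = Grammar(("S2", "B"), "S2",
                     (branch("S2", "S2", "B"), unpaired("S2"), unpaired("B")))
        child = breed(g1, g2)
        start_rules = {(r.kind, r.children) for r in child.rules_for("S")}
        assert start_rules == {
            (RuleKind.PAIR, ("S",)),
            (RuleKind.UNPAIRED, ()),
            (RuleKind.BRANCH, ("S", "B")),
        }
        # n + m + 2 non-terminals (here 1 + 1 + 2)
        assert len(child.nonterminals) == 4
        assert validate_normal_form(child) == []

    def test_child_derives_parent_structures(self, kh99p, rng):
        other = Grammar(("S2", "B"), "S2",
                        (branch("S2", "S2", "B"), pair("S2", "B"),
                         unpaired("S2"), unpaired("B")))
        child = breed(kh99p, other)
        uniform = ScfgParams.uniform(kh99p)
        uniform2 = ScfgParams.uniform(other)
        for parent, params in ((kh99p, uniform), (other, uniform2)):
            sampled = 0
            while sampled < 50:
                text = sample_structure(parent, params, rng, max_len=25)
                if text is None:
                    continue
                sampled += 1
                assert count_derivations(child, text) >= 1

    def test_self_breed_preserves_language(self, kh99p, rng):
        child = breed(kh99p, kh99p)
        uniform = ScfgParams.uniform(kh99p)
        for _ in range(100):
            text = sample_structure(kh99p, uniform, rng, max_len=20)
            if text is not None:
                assert count_derivations(child, text) >= 1


def _toy_records():
    data = [("GAAAC", "(...)"), ("AAAA", "...."), ("GGAAACC", "((...))"),
            ("ACGUA", ".(.)."), ("GCAAAAGC", "((....))")]
    return [
        StructuredSequence(str(k), s, parse_dotbracket(t))
        for k, (s, t) in enumerate(data)
    ]


class TestFitnessAndSelection:
    def test_mountain_fitness_zero_for_perfect_predictor(self):
        # degenerate: grammar that can only emit the trusted structures exactly
        records = [
            StructuredSequence("0", "GAC", parse_dotbracket("(.)")),
        ]
        g = Grammar(("S", "B"), "S", (pair("S", "B"), unpaired("B"), unpaired("S")))
        config = EvolutionConfig(fitness="mountain", prediction_method="cyk")
        assert evaluate_fitness(g, records, config) == 0.0

    def test_fscore_fitness_is_negated(self):
        records = [StructuredSequence("0", "GAC", parse_dotbracket("(.)"))]
        g = Grammar(("S", "B"), "S", (pair("S", "B"), unpaired("B"), unpaired("S")))
        config = EvolutionConfig(fitness="fscore", prediction_method="cyk")
        assert evaluate_fitness(g, records, config) == pytest.approx(-1.0)

    def test_composite_complexity_term_additive(self):
        # training structures keep B at unit spans, so B -> B B is never used
        # in any derivation: the trained probabilities and hence predictions
        # are identical and the fitness difference is exactly the complexity w
        records = [
            StructuredSequence("0", "GAC", parse_dotbracket("(.)")),
            StructuredSequence("1", "A", parse_dotbracket(".")),
        ]
        g = Grammar(("S", "B"), "S", (pair("S", "B"), unpaired("S"), unpaired("B")))
        w = 0.125
        config = EvolutionConfig(
            fitness="composite", composite_terms={"complexity_cost": w},
            prediction_method="cyk",
        )
        base = evaluate_fitness(g, records, config)
        bigger = g.add_rule(branch("B", "B", "B"))
        diff = evaluate_fitness(bigger, records, config) - base
        assert diff == pytest.approx(w)

    def test_unparseable_grammar_gets_sentinel(self):
        g = Grammar(("S", "B"), "S", (pair("S", "B"), unpaired("B")))
        records = [StructuredSequence("0", "AAAA", parse_dotbracket("...."))]
        config = EvolutionConfig()
        assert evaluate_fitness(g, records, config) == math.inf

    def test_selection_size_and_elitism(self, kh99p, rng):
        pop = [(kh99p, float(k)) for k in range(10)]
        survivors = select(pop, 4, rng)
        assert len(survivors) == 4
        assert any(f == 0.0 for _, f in survivors)  # best never eliminated

    def test_sentinel_worst_eliminated_first(self, kh99p, rng):
        pop = [(kh99p, 1.0)] * 5 + [(kh99p, math.inf)]
        survivors = select(pop, 5, rng)
        assert all(math.isfinite(f) for _, f in survivors)

    def test_selection_reproducible(self, kh99p):
        pop = [(kh99p, float(k)) for k in range(8)]
        s1 = select(pop, 3, np.random.default_rng(2))
        s2 = select(pop, 3, np.random.default_rng(2))
        assert [f for _, f in s1] == [f for _, f in s2]


class TestRunEvolution:
    def test_short_run_champion_monotone_and_reproducible(self):
        records = _toy_records()
        config = EvolutionConfig(
            generations=4, offspring_per_generation=4, seed=12,
            fitness="fscore", prediction_method="cyk",
        )
        s1 = run_evolution(records, None, config)
        s2 = run_evolution(records, None, config)
        champs = [h[1] for h in s1.history]
        assert all(b <= a for a, b in zip(champs, champs[1:]))
        assert [g for g, _ in s1.population] == [g for g, _ in s2.population]
        assert s1.champion == s2.champion
        assert len(s1.population) == config.population_size
        for g, _ in s1.population:
            assert validate_normal_form(g) == [] and PROTECTED_RULE in g.rules

    def test_invalid_generations_rejected(self):
        with pytest.raises(ValueError):
            run_evolution(_toy_records(), None, EvolutionConfig(generations=0))


class TestBruteForce:
    def test_enumeration_is_exactly_the_grammar_space(self):
        count = 0
        for g in itertools.islice(enumerate_two_nonterminal_grammars(), 500):
            count += 1
            assert PROTECTED_RULE in g.rules
            # shape violations only (an empty start is a counted grammar too)
            violations = [
                v for v in validate_normal_form(g) if "unproductive" not in v
            ]
            assert violations == []
        assert count == 500
        assert sum(1 for _ in enumerate_two_nonterminal_grammars()) == 16384

    def test_budgeted_evaluation(self):
        records = _toy_records()
        results = brute_force_space(records, records, budget=40)
        assert len(results) == 40
        sens = [rep.sensitivity for _, rep in results]
        assert sens == sorted(sens, reverse=True)
        # grammars deriving nothing get zero metrics
        empty = [rep for g, rep in results if not g.rules_for("S")]
        assert all(rep.sensitivity == 0.0 for rep in empty)


class TestLocalSearch:
    def test_neighbourhood_counts(self, kh99p):
        assert len(local_search_grammars(kh99p, "add1")) == 32
        assert len(local_search_grammars(kh99p, "add2")) == 496
        assert len(local_search_grammars(kh99p, "del1")) == 6

    def test_protected_rule_survives_deletion(self, kh99p):
        for g in local_search_grammars(kh99p, "del1"):
            assert PROTECTED_RULE in g.rules

    def test_evaluated_local_search(self, kh99p):
        records = _toy_records()
        results = local_search(kh99p, "del1", records, records)
        assert len(results) == 6
        for g, rep in results:
            assert 0.0 <= rep.sensitivity <= 1.0
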