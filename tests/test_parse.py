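import itertools
import math

import numpy as np
import pytest

from rnascfg.parse import (
    count_derivations,
    sample_derivation,
    sequence_cyk,
    sequence_inside,
    sequence_outside_posteriors,
    structure_cyk,
)

from _oracle import (
    all_dotbracket_strings,
    enumerate_derivations,
    oracle_posteriors,
    sequence_enumeration,
    tree_probability,
)


class TestStructureCyk:
    def test_best_derivation_probability(self, tg1):
        g, p = tg1
        logp, deriv = structure_cyk(g, "(.)", p)
        assert logp == pytest.approx(math.log(0.6))
        assert deriv.to_dotbracket() == "(.)"
        assert [r.kind.value for r in deriv.rule_multiset()] == ["pair", "unpaired"]

    def test_underivable_string_is_no_parse(self, tg1):
        g, p = tg1
        assert structure_cyk(g, "..", p) is None

    def test_empty_string_is_no_parse(self, tg1):
        g, p = tg1
        assert structure_cyk(g, "", p) is None

    def test_unweighted_parse_returns_some_derivation(self, tg2):
        g, _ = tg2
        _, deriv = structure_cyk(g, "...")
        assert deriv.to_dotbracket() == "..."


class TestCountDerivations:
    def test_ambiguous_string_counted(self, tg2):
        g, _ = tg2
        assert count_derivations(g, "...") == 2

    def test_underivable_string_counts_zero(self, tg1):
        g, _ = tg1
        assert count_derivations(g, "..") == 0

    def test_kh99p_sampled_structures_are_unambiguous(self, kh99p, synthetic_records):
        for rec in synthetic_records[:50]:
            assert count_derivations(kh99p, str(rec.structure)) == 1

    def test_cap_saturates(self, tg2):
        g, _ = tg2
        exact = count_derivations(g, "." * 12)
        assert exact > 5
        assert count_derivations(g, "." * 12, cap=5) == 5


class TestSampleDerivation:
    def test_unambiguous_grammar_ignores_seed(self, tg1):
        g, _ = tg1
        d1 = sample_derivation(g, "(.)", np.random.default_rng(0))
        d2 = sample_derivation(g, "(.)", np.random.default_rng(99))
        assert d1 == d2

    def test_uniform_over_derivations(self, tg2, rng):
        g, _ = tg2
        counts = {}
        for _ in range(4000):
            d = sample_derivation(g, "...", rng)
            key = tuple((n.rule, n.i, n.j) for n in d.iter_nodes())
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 2
        freq = min(counts.values()) / 4000
        # binomial 3 sigma around 0.5 at n=4000 is ~0.024
        assert abs(freq - 0.5) < 0.03

    def test_fixed_seed_reproducible(self, tg2):
        g, _ = tg2
        d1 = sample_derivation(g, "..(..)", np.random.default_rng(5))
        d2 = sample_derivation(g, "..(..)", np.random.default_rng(5))
        assert d1 == d2

    def test_underivable_raises(self, tg1, rng):
        g, _ = tg1
        with pytest.raises(ValueError):
            sample_derivation(g, "..", rng)


class TestSequenceInside:
    def test_single_derivation_hand_product(self, tg1):
        g, p = tg1
        _, total = sequence_inside(g, p, "A")
        assert total == pytest.approx(math.log(0.4 * 0.25))

    def test_total_at_least_viterbi(self, tg2):
        g, p = tg2
        _, total = sequence_inside(g, p, "ACG")
        best, _, _ = sequence_cyk(g, p, "ACG")
        assert total >= best

    def test_out_of_support_gives_minus_inf(self, tg_degenerate):
        g, p = tg_degenerate
        _, total = sequence_inside(g, p, "AC")
        assert total == -math.inf


class TestSequenceCyk:
    def test_best_structure_matches_enumeration(self, tg2):
        g, p = tg2
        logp, _, structure = sequence_cyk(g, p, "ACG")
        assert str(structure) == "(.)"
        assert logp == pytest.approx(math.log(0.2 * 0.5 * (1 / 16) * 0.25))

    def test_no_parse_when_no_branch_rules(self, tg1):
        g, p = tg1
        assert sequence_cyk(g, p, "AC") is None

    def test_deterministic_across_runs(self, toy_grammars):
        g, p = toy_grammars[3]
        r1 = sequence_cyk(g, p, "ACGUAC")
        r2 = sequence_cyk(g, p, "ACGUAC")
        assert r1[0] == r2[0] and r1[2] == r2[2]


class TestPosteriors:
    def test_degenerate_grammar_posterior(self, tg_degenerate):
        g, p = tg_degenerate
        post = sequence_outside_posteriors(g, p, "ACG")
        assert post.pair_prob[0, 2] == pytest.approx(1.0)
        assert post.unpaired_prob[1] == pytest.approx(1.0)

    def test_uniform_emissions_content_invariant(self, tg2):
        g, p = tg2
        a = sequence_outside_posteriors(g, p, "AAAA").pair_prob
        b = sequence_outside_posteriors(g, p, "GCGC").pair_prob
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_out_of_support_raises(self, tg_degenerate):
        g, p = tg_degenerate
        with pytest.raises(ValueError, match="support"):
            sequence_outside_posteriors(g, p, "AC")

    def test_q_complements_pair_mass(self, toy_grammars):
        g, p = toy_grammars[3]
        post = sequence_outside_posteriors(g, p, "GGGAAACCC")
        P, q = post.pair_prob, post.unpaired_prob
        np.testing.assert_allclose(q, 1.0 - P.sum(0) - P.sum(1), atol=1e-9)
        assert (q >= -1e-9).all()
        assert (P >= 0).all() and (P <= 1 + 1e-12).all()


class TestOracleEquivalence:
    """Exhaustive agreement with the brute-force derivation enumerator."""

    def test_structure_level_all_strings_up_to_6(self, toy_grammars):
        for g, p in toy_grammars:
            for n in range(1, 7):
                for text in all_dotbracket_strings(n):
                    trees = enumerate_derivations(g, text)
                    assert count_derivations(g, text) == len(trees)
                    result = structure_cyk(g, text, p)
                    if not trees:
                        assert result is None
                    else:
                        best = max(tree_probability(t, p) for t in trees)
                        assert result[0] == pytest.approx(math.log(best))

    def test_sequence_level_exhaustive_to_4_sampled_to_6(self, toy_grammars, rng):
        sequences = [
            "".join(c) for n in range(1, 5)
            for c in itertools.product("ACGU", repeat=n)
        ]
        for n in (5, 6):
            for _ in range(30):
                sequences.append("".join(rng.choice(list("ACGU"), size=n)))
        for g, p in toy_grammars:
            for seq in sequences:
                entries = sequence_enumeration(g, p, seq)
                total = sum(prob for *_, prob in entries)
                _, inside_total = sequence_inside(g, p, seq)
                cyk = sequence_cyk(g, p, seq)
                if not entries:
                    assert inside_total == -math.inf and cyk is None
                    continue
                assert inside_total == pytest.approx(math.log(total))
                best = max(prob for *_, prob in entries)
                assert cyk[0] == pytest.approx(math.log(best))
                # the returned structure must support a maximal derivation
                best_texts = {
                    text for text, _, prob in entries
                    if prob > best * (1 - 1e-12)
                }
                assert str(cyk[2]) in best_texts
                post = sequence_outside_posteriors(g, p, seq)
                np.testing.assert_allclose(
                    post.pair_prob, oracle_posteriors(g, p, seq), atol=1e-9
                )

    def test_unambiguous_likelihood_decomposes_over_structures(self, kh99p, toy_grammars):
        _, params = toy_grammars[3]
        seq = "GCAAAA"
        entries = sequence_enumeration(kh99p, params, seq)
        texts = [t for t, _, _ in entries]
        assert len(texts) == len(set(texts))  # one derivation per structure
        _, total = sequence_inside(kh99p, params, seq)
        assert total == pytest.approx(math.log(sum(p for *_, p in entries)))


class TestInvariances:
    def test_inside_total_invariant_under_nonterminal_renaming(self, tg1):
        from rnascfg.grammar import Grammar, ProductionRule

        g, p = tg1
        mapping = {"S": "X", "B": "Y"}
        g2 = Grammar(
            tuple(mapping[nt] for nt in g.nonterminals),
            mapping[g.start],
            tuple(
                ProductionRule(
                    mapping[r.lhs], r.kind, tuple(mapping[c] for c in r.children)
                )
                for r in g.rules
            ),
        )
        p2 = type(p)(
            rule_prob={
                ProductionRule(
                    mapping[r.lhs], r.kind, tuple(mapping[c] for c in r.children)
                ): v
                for r, v in p.rule_prob.items()
            },
            unpaired_emit=p.unpaired_emit,
            paired_emit=p.paired_emit,
        )
        _, t1 = sequence_inside(g, p, "ACG")
        _, t2 = sequence_inside(g2, p2, "ACG")
        assert t1 == pytest.approx(t2)
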