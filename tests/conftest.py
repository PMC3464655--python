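from __future__ import annotations

import numpy as np
import pytest

from rnascfg.grammar import (
    BASE_PAIRS,
    BASES,
    Grammar,
    ScfgParams,
    branch,
    builtin_grammar,
    pair,
    unpaired,
)
from rnascfg.sample import SamplerConfig, default_fixture, sample_records


def make_params(grammar: Grammar, rule_prob: dict) -> ScfgParams:
    return ScfgParams(
        rule_prob=dict(rule_prob),
        unpaired_emit={b: 0.25 for b in BASES},
        paired_emit={bp: 1.0 / 16.0 for bp in BASE_PAIRS},
    )


@pytest.fixture(scope="session")
def tg1():
    """S -> (B) | . ; B -> . — unambiguous, two derivable strings."""
    g = Grammar(("S", "B"), "S", (pair("S", "B"), unpaired("S"), unpaired("B")))
    p = make_params(
        g, {pair("S", "B"): 0.6, unpaired("S"): 0.4, unpaired("B"): 1.0}
    )
    return g, p


@pytest.fixture(scope="session")
def tg2():
    """S -> SS | . | (S) — ambiguous single-non-terminal grammar."""
    g = Grammar(("S",), "S", (branch("S", "S", "S"), unpaired("S"), pair("S", "S")))
    p = make_params(
        g,
        {branch("S", "S", "S"): 0.3, unpaired("S"): 0.5, pair("S", "S"): 0.2},
    )
    return g, p


@pytest.fixture(scope="session")
def tg_degenerate():
    """S -> (B) ; B -> . — derives exactly one string, '(.)'."""
    g = Grammar(("S", "B"), "S", (pair("S", "B"), unpaired("B")))
    p = make_params(g, {pair("S", "B"): 1.0, unpaired("B"): 1.0})
    return g, p


@pytest.fixture(scope="session")
def toy_grammars(tg1, tg2, tg_degenerate):
    kh = builtin_grammar("KH99p_synthetic", with_params=True)
    return [tg1, tg2, tg_degenerate, kh]


@pytest.fixture(scope="session")
def kh99p():
    return builtin_grammar("KH99p")


@pytest.fixture(scope="session")
def synthetic_records():
    """120 records sampled from the bundled KH99p fixture (length <= 40)."""
    grammar, params = default_fixture()
    return sample_records(SamplerConfig(grammar, params, 120, 40, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
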