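"""Structure prediction: CYK (maximum-likelihood derivation) and γ-weighted
maximum-expected-accuracy (MEA) posterior decoding.

MEA computes posterior base-pair probabilities p(i,j) and unpaired
probabilities q(i) by inside-outside, then finds the non-crossing structure
maximising

    sum_{(i,j) in pairs} γ·p(i,j)  +  sum_{unpaired i} q(i)

with a Nussinov-style dynamic program.  γ trades correct base pairs against
correct unpaired positions; γ=2 weights a pair by both of its positions, i.e.
maximises the expected number of correctly predicted positions.  The MEA
structure need not be derivable by the grammar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grammar import Grammar, ScfgParams
from .parse import PosteriorMatrix, sequence_cyk, sequence_outside_posteriors
from .structure import Structure

__all__ = ["Prediction", "predict_cyk", "predict_mea", "mea_structure"]


@dataclass(frozen=True)
class Prediction:
    """A predicted structure with its decoding method and score.

    ``failed=True`` means the grammar could not derive any structure for the
    sequence; the structure is then all-unpaired and the score is the sentinel
    (-inf for CYK log-probability, 0.0 for the MEA objective).
    """

    structure: Structure
    method: str  # "cyk" | "mea"
    score: float
    gamma: float | None = None
    failed: bool = False


def predict_cyk(grammar: Grammar, params: ScfgParams, sequence: str) -> Prediction:
    """Predict by maximum-likelihood derivation (CYK with backtracking)."""
    result = sequence_cyk(grammar, params, sequence)
    if result is None:
        return Prediction(
            structure=Structure(length=len(sequence)),
            method="cyk",
            score=-np.inf,
            failed=True,
        )
    logp, _, structure = result
    return Prediction(structure=structure, method="cyk", score=logp)


def mea_structure(posterior: PosteriorMatrix, gamma: float) -> tuple[Structure, float]:
    """Non-crossing structure maximising the γ-weighted expected accuracy.

    Deterministic tie-breaking: among objective-optimal structures prefer the
    one with fewer pairs; remaining ties are resolved by pairing the leftmost
    position with its smallest admissible partner.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    n = posterior.n
    P = posterior.pair_prob
    q = posterior.unpaired_prob
    M = np.zeros((n + 2, n + 2))       # M[i][j]: best objective on [i, j)
    NP = np.zeros((n + 2, n + 2), dtype=np.int64)  # min pairs among optima

    for length in range(1, n + 1):
        for i in range(n - length + 1):
            j = i + length
            best = q[i] + M[i + 1][j]
            best_np = NP[i + 1][j]
            if length >= 2:
                ts = np.arange(i + 1, j)
                vals = (gamma * P[i, i + 1 : j] + M[i + 1, i + 1 : j]) + M[i + 2 : j + 1, j]
                pair_np = 1 + NP[i + 1, i + 1 : j] + NP[i + 2 : j + 1, j]
                vmax = vals.max()
                if vmax > best:
                    best = vmax
                    best_np = pair_np[vals == vmax].min()
                elif vmax == best:
                    best_np = min(best_np, pair_np[vals == vmax].min())
            M[i][j] = best
            NP[i][j] = best_np

    pairs: list[tuple[int, int]] = []

    def _traceback(i: int, j: int) -> None:
        while i < j:
            target = M[i][j]
            target_np = NP[i][j]
            chosen = None
            for t in range(i + 1, j):
                val = (gamma * P[i, t] + M[i + 1][t]) + M[t + 1][j]
                if val == target and 1 + NP[i + 1][t] + NP[t + 1][j] == target_np:
                    chosen = t
                    break
            if chosen is not None:
                pairs.append((i, chosen))
                _traceback(i + 1, chosen)
                i = chosen + 1
            else:
                # unpaired option; matches by construction
                i += 1

    _traceback(0, n)
    structure = Structure(length=n, pairs=frozenset(pairs))
    return structure, float(M[0][n])


def predict_mea(
    grammar: Grammar,
    params: ScfgParams,
    sequence: str,
    gamma: float = 2.0,
    posterior: PosteriorMatrix | None = None,
) -> Prediction:
    """Predict by γ-weighted posterior decoding.

    A precomputed ``posterior`` may be supplied (e.g. when sweeping γ).
    Sequences outside the grammar's support yield ``failed=True`` with the
    all-unpaired structure.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if posterior is None:
        try:
            posterior = sequence_outside_posteriors(grammar, params, sequence)
        except ValueError:
            return Prediction(
                structure=Structure(length=len(sequence)),
                method="mea",
                score=0.0,
                gamma=gamma,
                failed=True,
            )
    structure, score = mea_structure(posterior, gamma)
    return Prediction(structure=structure, method="mea", score=score, gamma=gamma)
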