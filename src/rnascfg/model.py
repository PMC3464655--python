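"""A scikit-learn style estimator wrapping SCFG training and decoding.

``ScfgStructurePredictor`` fits grammar parameters from RNA sequences (and,
for supervised training, their trusted dot-bracket structures) and predicts
secondary structures for new sequences.  It follows the sklearn estimator
protocol (``get_params``/``set_params``, ``fit``/``predict``/``score``,
fitted attributes with trailing underscores) so it composes with pipelines
and model selection.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .decode import predict_cyk, predict_mea
from .grammar import Grammar, builtin_grammar
from .metrics import MetricReport, aggregate
from .parse import sequence_outside_posteriors
from .structure import Structure, StructuredSequence, parse_dotbracket
from .train import em_train, supervised_train

__all__ = ["ScfgStructurePredictor"]


class ScfgStructurePredictor(BaseEstimator):
    """Predict RNA secondary structure with a stochastic context-free grammar.

    Parameters
    ----------
    grammar : str or Grammar, default "KH99p"
        The grammar (a bundled name such as "KH99p" or "GG6", or a
        :class:`~rnascfg.grammar.Grammar`).
    training : {"cyk", "io"}, default "cyk"
        "cyk": supervised multinomial counting from trusted structures
        (random-derivation convention for ambiguous grammars).
        "io": inside-outside EM on the sequences alone.
    decoding : {"mea", "cyk"}, default "mea"
        Posterior (maximum expected accuracy) or maximum-likelihood decoding.
    gamma : float, default 2.0
        MEA trade-off between base pairs and unpaired positions; 2 maximises
        the expected number of correctly predicted positions.
    pseudocount : float, default 0.0
        Additive smoothing for supervised counting.
    max_iters, tol : EM stopping rule (training="io").
    random_state : int or None
        Seeds derivation sampling for ambiguous grammars and EM jitter.

    Attributes
    ----------
    grammar_ : Grammar            resolved grammar
    params_ : ScfgParams          fitted probabilities
    loglik_trace_ : list[float]   EM log-likelihood trace (training="io")
    """

    def __init__(
        self,
        grammar: str | Grammar = "KH99p",
        training: str = "cyk",
        decoding: str = "mea",
        gamma: float = 2.0,
        pseudocount: float = 0.0,
        max_iters: int = 100,
        tol: float = 1e-4,
        random_state: int | None = None,
    ):
        self.grammar = grammar
        self.training = training
        self.decoding = decoding
        self.gamma = gamma
        self.pseudocount = pseudocount
        self.max_iters = max_iters
        self.tol = tol
        self.random_state = random_state

    def _records(self, X: Sequence[str], y) -> list[StructuredSequence]:
        if y is None:
            raise ValueError("supervised training needs structures y")
        records = []
        for k, (seq, struct) in enumerate(zip(X, y)):
            if isinstance(struct, str):
                struct = parse_dotbracket(struct)
            records.append(StructuredSequence(str(k), seq, struct))
        return records

    def fit(self, X: Sequence[str], y=None) -> "ScfgStructurePredictor":
        """Fit parameters from sequences ``X`` (and structures ``y``).

        ``y`` holds dot-bracket strings (or Structures); it is required for
        ``training="cyk"`` and ignored by EM except for length validation.
        """
        if self.training not in ("cyk", "io"):
            raise ValueError("training must be 'cyk' or 'io'")
        if self.decoding not in ("cyk", "mea"):
            raise ValueError("decoding must be 'cyk' or 'mea'")
        self.grammar_ = (
            builtin_grammar(self.grammar) if isinstance(self.grammar, str) else self.grammar
        )
        rng = np.random.default_rng(self.random_state)
        if self.training == "cyk":
            records = self._records(X, y)
            self.params_ = supervised_train(
                self.grammar_, records, pseudocount=self.pseudocount, rng=rng
            )
            self.loglik_trace_ = None
        else:
            records = [
                StructuredSequence(str(k), seq, Structure(length=len(seq)))
                for k, seq in enumerate(X)
            ]
            self.params_, self.loglik_trace_ = em_train(
                self.grammar_, records, max_iters=self.max_iters, tol=self.tol, rng=rng
            )
        return self

    def predict(self, X: Sequence[str]) -> list[str]:
        """Predict one dot-bracket structure per sequence."""
        self._check_fitted()
        out = []
        for seq in X:
            if self.decoding == "mea":
                pred = predict_mea(self.grammar_, self.params_, seq, self.gamma)
            else:
                pred = predict_cyk(self.grammar_, self.params_, seq)
            out.append(str(pred.structure))
        return out

    def predict_proba(self, X: Sequence[str]) -> list[np.ndarray]:
        """Posterior base-pair probability matrix p(i, j) per sequence."""
        self._check_fitted()
        return [
            sequence_outside_posteriors(self.grammar_, self.params_, seq).pair_prob
            for seq in X
        ]

    def score(self, X: Sequence[str], y) -> float:
        """Micro-averaged base-pair F-score against trusted structures ``y``."""
        report = self.report(X, y)
        return report.fscore

    def report(self, X: Sequence[str], y) -> MetricReport:
        self._check_fitted()
        records = self._records(X, y)
        preds = [parse_dotbracket(s) for s in self.predict(X)]
        return aggregate(records, preds)

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise ValueError("this ScfgStructurePredictor instance is not fitted yet")
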