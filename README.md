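# rnascfg

RNA secondary structure prediction with **stochastic context-free grammars
(SCFGs)**, plus automatic search over grammar space.

An SCFG is a context-free grammar `(N, V, P, S)` with a probability
distribution over the production rules of each non-terminal. Choosing the
terminal alphabet `{ ( , ) , . }`, derivations generate dot-bracket strings
that uniquely define pseudoknot-free secondary structures; a generative model
for sequences then allocates nucleotides per site from a 4-way unpaired
distribution and a 16-way ordered base-pair distribution. All grammars here
are restricted to the *double emission normal form*

```
T -> U V        (branching)
T -> .          (one unpaired position)
T -> ( U )      (both partners of a base pair, emitted together)
```

which captures branching, unpaired, and paired positions while excluding the
unit and epsilon rules that admit infinitely many derivations. For `m`
non-terminals there are `m³ + m² + m` possible rules and hence
`2^(m³ + m² + m)` grammars — 16,384 at `m = 2`, over 500 billion at `m = 3` —
which is why this package pairs the inference machinery with evolutionary,
brute-force, and local search over that space.

What the library provides:

- **Inference** — CYK (maximum-likelihood derivation, hence structure) and
  the inside–outside algorithms, giving total sequence likelihoods and
  posterior base-pair probabilities `p(i,j)`;
- **Decoding** — maximum-expected-accuracy (MEA) posterior decoding that
  maximises `Σ γ·p(i,j) + Σ q(i)` over non-crossing structures, with the
  pair/unpaired trade-off `γ` (default 2: a correct pair scores both of its
  positions);
- **Training** — supervised multinomial counting from trusted structures
  (drawing one derivation uniformly at random for ambiguous grammars) and
  inside–outside EM on sequences alone;
- **Diagnostics** — heuristic tests for grammar *ambiguity* (some structure
  with more than one derivation) and *completeness* (derives every structure
  whose hairpin loops have ≥ 2 unpaired positions);
- **Search** — an evolutionary algorithm (16-grammar seed population, five
  mutation operators, language-union breeding, stochastic elimination with
  one-elite selection), exhaustive enumeration of all 16,384 two-non-terminal
  grammars, and add/delete local search;
- **Data** — Vienna-style dot-bracket record I/O, benchmark-style filtering
  (duplicate sequences, >80% base-pair similarity, pseudoknots), and a
  synthetic-data generator that samples (sequence, structure) pairs from any
  parameterised grammar;
- **Bundled grammars** — `KH99p` (the Knudsen–Hein/Pfold grammar in this
  normal form) and the search-derived grammars `GG1`–`GG6`.

Metrics follow the base-pair convention: sensitivity `TP/(TP+FN)`, PPV
`TP/(TP+FP)`, F-score `2TP/(2TP+FN+FP)`, micro-averaged over a dataset, plus
the L1 mountain metric.

## Worked example

Everything runs on synthetic data sampled from the bundled parameterised
KH99p fixture, so no downloads are needed:

```python
from rnascfg import ScfgStructurePredictor
from rnascfg.sample import SamplerConfig, default_fixture, sample_records
from rnascfg.structure import to_dotbracket

grammar, params = default_fixture()
records = sample_records(SamplerConfig(grammar, params,
                                       n_records=200, max_len=60, seed=42))
X = [r.sequence for r in records]
y = [to_dotbracket(r.structure) for r in records]

model = ScfgStructurePredictor(grammar="KH99p", training="cyk",
                               decoding="mea", gamma=2.0, random_state=0)
model.fit(X[:150], y[:150])
report = model.report(X[150:], y[150:])
print(f"test F-score {report.fscore:.3f}  "
      f"(sensitivity {report.sensitivity:.3f}, PPV {report.ppv:.3f})")
```

prints

```
test F-score 0.453  (sensitivity 0.395, PPV 0.531)
```

i.e. on 50 held-out synthetic sequences, 39.5% of the true base pairs are
recovered and 53.1% of the predicted pairs are correct (34 true positives, 30
false positives, 52 false negatives summed over the test records). A single
55-nucleotide prediction next to its true structure:

```
>>> print(model.predict([X[166]])[0]); print(y[166])
((((.....((..))......))))(((..........((((((..)))))))))
.(.(.(..((.(.(.(.......))))(.(..))..))((((((..)))))).))
```

The same pipeline is available from the shell:

```bash
rnascfg sample --n 200 --max-len 60 --seed 42 --out synth.db
rnascfg train --grammar KH99p --data synth.db --method cyk --out kh99p.trained.grm
rnascfg predict --grammar kh99p.trained.grm --method mea --gamma 2.0 \
        --in synth.db --out pred.db
rnascfg evaluate --pred pred.db --truth synth.db
rnascfg check --grammar GG4 --property both --max-len 14
rnascfg evolve --train synth.db --seed 3 --out rundir/
```

`rnascfg check` on GG4, for instance, reports it ambiguous and *incomplete*,
with witness structures (such as `..` and `(...)(...)(...)(...)`) that it
cannot derive.

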