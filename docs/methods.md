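# Methods

## Model

A structure-generating SCFG is a context-free grammar over the terminals
`(`, `)`, `.` with a probability distribution over each non-terminal's rules.
Every grammar in this package is in the *double emission normal form*: rules
are `T -> U V`, `T -> .`, or `T -> ( U )`. The pair rule emits both partners
of a base pair in one production, so a single rule application carries the
joint (16-way, ordered) paired-nucleotide distribution; unpaired positions
carry a 4-way distribution. Both emission tables are global — one per model,
not per rule or per non-terminal — matching a generative story in which the
grammar first emits a dot-bracket string and nucleotides are then allocated
per site by paired/unpaired status. Stacking-style context-dependent
emissions are out of scope.

Unit (`T -> U`) and epsilon rules are excluded: they allow cyclic
productions and hence countably many derivations of a string. Consequently
the empty string is underivable, adjacent positions can never pair, and every
derivable string has at least one position. Grammars that exist in other
normal forms (e.g. the Knudsen–Hein Pfold grammar) are bundled here in their
double-emission re-expression (`KH99p`).

Probabilities of a derivation multiply rule probabilities and, at sequence
level, emission probabilities. The joint model is
`P(derivation, sequence) = Π rule_prob × Π emissions`.

## Dynamic programs

All DPs share half-open 0-based spans `[i, j)` and run in log space with
`-inf` for impossibility (`NO_PARSE` is the value `None`, never an
exception). Complexity is `O(|rules| · n³)` time, `O(|N| · n²)` space; the
split-point loop is vectorised with numpy. No banding, no minimum-hairpin
constraint is imposed by the engine — the grammar alone controls which
structures are derivable.

- **Structure-level** (input: dot-bracket text): derivation counting (sum of
  products), best-derivation CYK, and uniform derivation sampling via
  count-weighted stochastic backtracking. Counts use float64 tables
  saturated per cell at a cap (exact below 2^52); uniform sampling is
  therefore exact unless a string has astronomically many derivations, in
  which case it is uniform up to that saturation.
- **Sequence-level** (input: nucleotides): Viterbi CYK with backtracking,
  inside, outside, posterior base-pair probabilities
  `p(i,j) = Σ_{T->(U)} outside(T,[i,j+1]) · rule · emit(x_i,x_j) ·
  inside(U,[i+1,j)) / Z`, and expected rule/emission counts for EM.
  `q(i) = 1 - Σ_j p(·)` by definition (every position is paired or unpaired
  in every derivation), so `q` may carry ~1e-9 of negative rounding slack.

CYK tie-breaking is deterministic: pair/unpaired rules in grammar-file order
first, then split points ascending, then branch rules in grammar order.
Backtracking recomputes option scores with the same floating-point
association as the forward pass, so the argmax is reproduced exactly.

## Decoding

MEA decoding maximises `Σ_{(i,j)∈pairs} γ·p(i,j) + Σ_{unpaired} q(i)` over
all non-crossing structures by a Nussinov-style DP. `γ` (default 2) is the
pair/unpaired trade-off; `γ = 2` makes a correct pair worth its two
positions, i.e. maximises the expected number of correctly predicted
positions. The decoded structure need not be derivable by the grammar — an
incomplete grammar can still, via its posteriors, support any non-crossing
prediction. No pair-eligibility pre-filter is applied; the DP decides.
Tie-break: maximise the objective; among optima prefer fewer pairs (a second
DP table tracks the minimum pair count among optima); remaining ties pair the
leftmost position with its smallest admissible partner, which realises
lexicographically-least dot-bracket output in the common cases.

## Training

- **Supervised ("CYK") training**: each trusted structure is parsed once and
  rule usages become multinomial counts; emission counts come from the
  trusted paired/unpaired status. For ambiguous grammars the derivation used
  is drawn *uniformly at random* among all derivations of the structure (the
  sampling law is a choice — nothing in the model prefers one derivation);
  for unambiguous grammars no randomness is consumed. Underivable records
  are skipped with a logged count; an all-skipped dataset is an error.
  Pseudocount smoothing defaults to 0. Non-terminals with zero total count
  fall back to the uniform distribution (logged).
- **EM ("IO") training**: inside–outside expected counts on the sequences
  alone (trusted structures are ignored), renormalised each iteration;
  initialisation is uniform, with optional seeded ±jitter to break symmetry
  (off by default); stopping at `max_iters` (default 100) or when the
  log-likelihood improves by less than `tol` (default 1e-4). The trace is
  monotone non-decreasing up to 1e-8 floating-point slack. Sequences outside
  the grammar's support are excluded with a warning.

## Diagnostics

Ambiguity and completeness are undecidable in general, so both tests are
heuristic with explicit bounds:

- **Ambiguity**: exhaustive derivation counting over every derivable string
  up to length 10 (string-set DP with counts capped at 2), then up to 1,000
  structures sampled from uniform-rule derivations up to length 30, each
  re-counted. Positive verdicts carry verified witnesses; negative verdicts
  hold only up to the bound.
- **Completeness**: exhaustive enumeration of all valid structures of length
  **2..14** (default) whose hairpins all have ≥ 2 unpaired positions,
  compared against the grammar's derivable-string sets. Length-1 (`.`) is
  deliberately exempt: a lone unpaired base carries no structural
  information, and several grammars that are complete for every structure of
  length ≥ 2 (e.g. GG3, whose start symbol has no direct unpaired rule)
  would otherwise be misclassified relative to their published
  characterisation. Bounds above 18 require sampling mode.

With these defaults the seven bundled grammars reproduce their published
verdict pattern: KH99p unambiguous and complete; GG1–GG6 all ambiguous; GG4
and GG5 incomplete (GG4's witnesses include `..` and the documented
`(...)(...)(...)(...)`; GG5's include `(..)`), the others complete.

## Evolutionary search

- **Initial population**: the 16 grammars `S -> SS|SB|BS|BB|(S)|.`,
  `B -> .` with each of the 2⁴ subsets of branch rules excluded.
- **Mutations** (weights, defaults in parentheses): start-symbol change
  (0.05); rule addition/deletion (0.50, split 4:1 toward addition — adding
  too slowly starves structural development, deleting almost always hurts);
  new non-terminal with two rules guaranteeing reachability and a non-empty
  rule set (0.15); duplication of an existing non-terminal's rule set under
  a new name (0.10); rewiring one or both children of a branch or pair rule
  (0.20). `B -> .` is protected throughout, and deletion never empties a
  non-terminal's rule set (resampled instead).
- **Breeding** forms a child whose start rules are the union of both
  parents' start rules; each parent's non-terminals (other than the shared
  `B`) are renamed apart and references to the parent's start are redirected
  to the new start, so the child derives every string either parent can.
- **Fitness** (lower is better): summed mountain-metric distance, or negated
  sensitivity/PPV/F-score, or a composite adding a per-failure penalty, a
  complexity cost `w·|rules|`, and a reward for the longest exactly-predicted
  record. Grammars that parse no training structure get an infinite
  sentinel. Training and prediction methods inside fitness evaluation are
  configurable (supervised/EM × CYK/MEA).
- **Selection**: repeated single eliminations with probability proportional
  to `fitness − best + 1e-6` (scale-free, never stalls), infinite-fitness
  members eliminated first, and size-1 elitism so the best grammar always
  survives — hence a monotone champion trace. Whether the original procedure
  protected its champion is not documented; elitism is this package's
  choice.
- **Reproducibility**: one `numpy` generator seeded from the config drives
  every stochastic step (mutation, breeding, selection, derivation
  sampling), and per-run fitness caching is keyed by grammar identity, so a
  seed fixes the entire genealogy.

Brute force enumerates all 2¹⁴ = 16,384 subsets of the 14 rules over two
non-terminals (plus the fixed, unreferenced `B -> .`); start symbols that
derive nothing are scored zero without training. Local search enumerates
one-rule additions (32 for KH99p), unordered two-rule additions (496), and
single deletions with `B -> .` protected (6). A figure caption in the
original description of this neighbourhood gives 961 for two added rules;
the body text's 496 = C(32, 2) is the count used here.

## Synthetic data

The generator emulates the model's own generative process: a leftmost
stochastic derivation of a structure (rejected, not renormalised, when the
sentential form's guaranteed minimal yield exceeds `max_len`, and retried up
to `max_attempts`), then per-site nucleotide allocation. The bundled fixture
is KH99p with hand-set probabilities — branch-moderate, unpaired-heavy, with
expected yield ≈ 9 and a Watson-Crick/wobble-dominated pair table; the
parameters are synthetic, not trained on any dataset. Synthetic data
reproduces the model's assumptions exactly, so passing tests demonstrate
correctness of inference and search mechanics, **not** predictive accuracy
on real RNA: real structures violate the independence of pair emissions,
contain non-canonical and pseudoknotted interactions, and have length/family
spectra this sampler does not imitate. Published benchmark accuracies
require the curated datasets and are intentionally not reproduced here.

## Problem sizes used in the checks

Chosen as the package's own test scale: oracle equivalence is exhaustive
over all dot-bracket strings to length 6 and all sequences to length 4, with
a seeded sample at lengths 5–6 (the brute-force enumerator, not the DP, is
the limiting factor); parameter recovery uses 500 records of length ≤ 60
(±0.05 tolerance ≈ 3σ of the multinomial sampling error); EM monotonicity
uses 50 sequences of length ≤ 40; the γ sweep uses the full 100-point grid
(0.05..5.00 step 0.05) on 40 records; evolution mechanics use population 16,
30 generations, 40 records of length ≤ 40, with seed-reproducibility
verified on 5-generation runs.

## Known limitations

- Single-sequence prediction only; no comparative/phylogenetic extension.
- No pseudoknots (inherent to context-free structure grammars).
- Global emission tables; no stacking or context-dependent emissions.
- Heuristic diagnostics can certify presence, never absence, of ambiguity
  or incompleteness.
- Uniform derivation sampling saturates above 2^52 derivations per string.
- MEA lexicographic tie-breaking is best-effort beyond the pair-count rule.
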