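# Synthetic sampling fixture: KH99p with hand-set probabilities chosen so that
# stochastic derivations terminate with short expected yield (~9 positions)
# and emissions favour Watson-Crick and wobble pairs.  These parameters are
# NOT trained on any dataset; they exist to generate synthetic benchmarks.
start: A
A -> B A [0.40] | . [0.40] | ( C ) [0.20]
B -> . [0.80] | ( C ) [0.20]
C -> B A [0.60] | ( C ) [0.40]
unpaired: A 0.30 C 0.22 G 0.22 U 0.26
paired: AA 0.002 AC 0.002 AG 0.002 AU 0.17 CA 0.002 CC 0.002 CG 0.24 CU 0.002 GA 0.002 GC 0.24 GG 0.002 GU 0.08 UA 0.17 UC 0.002 UG 0.08 UU 0.002
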