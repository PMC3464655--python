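# Found with the CYK evolutionary search; strong F-score performer.
start: A
A -> D E | A B | B A | A H | . | ( F ) | ( H )
B -> .
C -> ( H )
D -> B B | A C
E -> . | ( H )
F -> F B | C F | .
G -> G H | ( H ) | ( C )
H -> F A | A F | H H | ( B ) | ( H )
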