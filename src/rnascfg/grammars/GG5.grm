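# Found with the CYK evolutionary search.
start: A
A -> D A | C C | . | ( B )
B -> .
C -> A A | H F | ( G )
D -> . | ( E )
E -> ( F )
F -> F B | B F | A A | . | ( A ) | ( F )
G -> ( E )
H -> B G
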