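# Found with the CYK evolutionary search; incomplete but effective.
start: A
A -> C C | C B | B C | E C | ( A ) | ( E )
B -> .
C -> C B | B B | ( A )
D -> G C | ( C )
E -> A B | C D | .
F -> A B
G -> F B
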