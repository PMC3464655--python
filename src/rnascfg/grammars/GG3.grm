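# Found with the posterior-decoding evolutionary search.
start: A
A -> A B | B A | B B | A A | D D | ( A ) | ( B ) | ( C ) | ( D )
B -> .
C -> A A | . | ( D )
D -> C D | B D | ( A ) | ( C )
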