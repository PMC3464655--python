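# Dense grammar found with the posterior-decoding evolutionary search.
start: A
A -> A A | A B | B A | B B | C B | B C | . | ( B ) | ( C )
B -> .
C -> A A | A B | B A | B B | B C | C A | C B | . | ( A ) | ( B ) | ( C )
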