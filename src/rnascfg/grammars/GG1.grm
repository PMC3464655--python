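# KH99p with two rules added (A -> A A and A -> ( A )); found by local search.
start: A
A -> A A | B A | . | ( A ) | ( C )
B -> . | ( C )
C -> B A | ( C )
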