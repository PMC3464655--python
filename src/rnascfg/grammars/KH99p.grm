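# KH99 (the Pfold grammar) re-expressed in the double emission normal form.
start: A
A -> B A | . | ( C )
B -> . | ( C )
C -> B A | ( C )
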