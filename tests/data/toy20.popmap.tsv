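a1	A
a2	A
a3	A
b1	B
b2	B
b3	B
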