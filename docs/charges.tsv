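nucleobase	code	First	Second	Third
Adenine	A	0.417	-0.514	0.228
Uracil	U	-0.506	0.408	-0.471
Guanine	G	-0.490	0.414	0.413
Cytosine	C	0.379	-0.558	-0.476
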