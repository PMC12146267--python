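step	ko	gene
Nar	K00370	narG
Nar	K00371	narH
Nar	K00374	narI
Nar	K02567	napA
Nar	K02568	napB
Nir	K00368	nirK
Nir	K15864	nirS
Nor	K04561	norB
Nor	K02305	norC
Nos	K00376	nosZ
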