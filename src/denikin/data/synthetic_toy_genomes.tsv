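genome	K00370	K00368	K15864	K04561	K02305	K00376	K02567
g01	2	1	0	1	1	1	0
g02	1	0	1	2	0	1	1
g03	1	1	0	1	0	2	0
g04	1	0	0	1	1	1	0
g05	1	0	0	0	0	0	1
g06	0	1	0	1	0	0	0
g07	2	1	0	1	1	0	0
g08	0	0	0	0	0	1	0
g09	1	1	0	0	0	0	0
g10	0	0	1	0	0	1	0
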