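location	country	latitude	longitude
De Kwakel	The Netherlands	52.2391	4.794
Krabbendam	The Netherlands	52.7318	4.7037
Wageningen	The Netherlands	51.9869	5.6644
Pulpi	Spain	37.3978	-1.7333
Eyragues	France	43.851	4.8296
Berurim	Israel	31.7712	34.77
Konan	Japan	34.9	136.1
Sansai	Thailand	18.9749	98.9879
Maewang	Thailand	18.6306	98.84
Bahia Blanca	Argentina	-39.3667	-62.6333
Progreso	Uruguay	-34.6163	-56.2232
Salto Grande	Uruguay	-31.2722	-57.8908
Tulancingo de Bravo	Mexico	20.1036	-98.3755
Huron	USA	36.28	-120.0814
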