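species	subfamily	site	n_individuals	reads_total
Chironomus australis	Chironominae	HW09	100	5318
Chironomus australis	Chironominae	LE09	1	318
Chironomus australis	Chironominae	MC09	0	2
Chironomus australis	Chironominae	ME09	18	2370
Chironomus australis	Chironominae	RL09	1	394
Chironomus australis	Chironominae	SK09	1	8
Chironomus australis	Chironominae	UK09	71	5519
Chironomus cloacalis	Chironominae	HW09	18	998
Chironomus cloacalis	Chironominae	LE09	11	1580
Chironomus cloacalis	Chironominae	ME09	1	79
Chironomus cloacalis	Chironominae	RL09	1	23
Chironomus cloacalis	Chironominae	UK09	5	511
Chironomus duplex	Chironominae	HW09	6	405
Chironomus duplex	Chironominae	LE09	3	149
Chironomus duplex	Chironominae	ME09	1	253
Chironomus duplex	Chironominae	RL09	3	225
Chironomus duplex	Chironominae	UK09	6	2327
Chironomus februarius	Chironominae	HW09	22	1104
Chironomus februarius	Chironominae	LE09	6	821
Chironomus februarius	Chironominae	RL09	20	861
Chironomus februarius	Chironominae	SK09	0	1
Chironomus februarius	Chironominae	UK09	2	82
Chironomus nepeanensis	Chironominae	UK09	1	298
Chironomus oppositus	Chironominae	BR08	3	35
Chironomus oppositus	Chironominae	DB09	2	603
Chironomus oppositus	Chironominae	GC09	1	934
Chironomus oppositus	Chironominae	LE09	57	6197
Chironomus oppositus	Chironominae	MC09	2	815
Chironomus oppositus	Chironominae	RL09	22	780
Chironomus oppositus	Chironominae	SK09	31	4803
Chironomus oppositus	Chironominae	UK09	1	0
Chironomus pseudoppositus	Chironominae	RL09	3	96
Chironomus tepperi	Chironominae	LE09	3	166
Chironomus tepperi	Chironominae	RL09	1	6
Cladopelma sp.1	Chironominae	LE09	0	4
Cladopelma sp.1	Chironominae	MC09	2	869
Cladopelma sp.1	Chironominae	UK09	1	10
Cladopelma sp.2	Chironominae	RL09	8	292
Cladotanytarsus australomancus	Chironominae	DB09	1	16
Cladotanytarsus australomancus	Chironominae	MC09	14	4239
Cladotanytarsus sp.C	Chironominae	BR08	1	7
Dicrotendipes pseudoconjunctus	Chironominae	DB09	4	999
Dicrotendipes pseudoconjunctus	Chironominae	HW09	3	100
Dicrotendipes pseudoconjunctus	Chironominae	LE09	6	479
Dicrotendipes pseudoconjunctus	Chironominae	MC09	1	1064
Dicrotendipes pseudoconjunctus	Chironominae	ME09	21	4724
Dicrotendipes pseudoconjunctus	Chironominae	RL09	6	198
Dicrotendipes pseudoconjunctus	Chironominae	SK09	1	579
Dicrotendipes septemmaculatus	Chironominae	DB09	0	1
Dicrotendipes septemmaculatus	Chironominae	HW09	1	17
Dicrotendipes sp.4	Chironominae	RL09	1	18
Dicrotendipes sp.4	Chironominae	SK09	2	895
Dicrotendipes sp.A	Chironominae	GC09	2	1877
Kiefferulus cornishi	Chironominae	GC09	1	686
Kiefferulus cornishi	Chironominae	ME09	1	29
Kiefferulus cornishi	Chironominae	SK09	4	516
Kiefferulus cornishi	Chironominae	UK09	4	75
Kiefferulus intertinctus	Chironominae	DB09	7	581
Kiefferulus intertinctus	Chironominae	GC09	3	1171
Kiefferulus intertinctus	Chironominae	HW09	1	30
Kiefferulus intertinctus	Chironominae	LE09	2	32
Kiefferulus intertinctus	Chironominae	ME09	1	177
Kiefferulus intertinctus	Chironominae	SK09	4	1737
Kiefferulus intertinctus	Chironominae	UK09	1	236
Kiefferulus martini	Chironominae	LE09	1	168
Kiefferulus martini	Chironominae	RL09	1	18
Microchironomus forcipatus	Chironominae	RL09	1	7
Parachironomus delinificus	Chironominae	BR08	1	430
Parachironomus delinificus	Chironominae	LE09	1	10
Parachironomus sp.3	Chironominae	BR08	3	324
Paratanytarsus grimmii	Chironominae	GC09	1	308
Paratanytarsus grimmii	Chironominae	LE09	3	264
Paratanytarsus grimmii	Chironominae	SK09	5	1483
Paratanytarsus sp.D	Chironominae	ME09	1	7
Polypedilum convexum	Chironominae	BR08	3	332
Polypedilum nubifer	Chironominae	HW09	9	401
Polypedilum nubifer	Chironominae	UK09	1	63
Polypedilum sp.C	Chironominae	DB09	43	2367
Polypedilum sp.C	Chironominae	HW09	0	2
Polypedilum sp.C	Chironominae	MC09	2	929
Polypedilum sp.E	Chironominae	MC09	1	284
Polypedilum sp.E	Chironominae	UK09	1	9
Riethia stictoptera	Chironominae	BR08	1	913
Riethia stictoptera	Chironominae	DB09	6	905
Tanytarsus inextentus	Chironominae	DB09	1	22
Tanytarsus inextentus	Chironominae	RL09	1	5
Ablabesmyia sp.2	Tanypodinae	BR08	1	46
Coelopynia sp.1	Tanypodinae	BR08	1	26
Coelopynia sp.1	Tanypodinae	LE09	0	1
Paramerina sp.4	Tanypodinae	DB09	1	74
Procladius paludicola	Tanypodinae	BR08	11	1702
Procladius paludicola	Tanypodinae	DB09	9	349
Procladius paludicola	Tanypodinae	HW09	1	18
Procladius paludicola	Tanypodinae	MC09	0	1
Procladius paludicola	Tanypodinae	UK09	2	95
Procladius sp.1	Tanypodinae	DB09	4	1382
Procladius sp.2	Tanypodinae	BR08	39	4609
Procladius sp.2	Tanypodinae	GC09	0	4
Procladius villosimanus	Tanypodinae	HW09	5	664
Procladius villosimanus	Tanypodinae	LE09	2	285
Procladius villosimanus	Tanypodinae	ME09	2	1392
Procladius villosimanus	Tanypodinae	RL09	30	6660
Botryocladius sp.1	Orthocladiinae	BR08	1	96
Corynoneura scutellata	Orthocladiinae	ME09	2	16
Corynoneura scutellata	Orthocladiinae	SK09	1	3
Cricotopus albitarsis	Orthocladiinae	GC09	4	156
Cricotopus annuliventris	Orthocladiinae	ME09	1	27
Cricotopus sp.1	Orthocladiinae	GC09	1	3
Cricotopus sp.2	Orthocladiinae	BR08	4	31
Cricotopus sp.2	Orthocladiinae	GC09	19	3930
Cricotopus sp.2	Orthocladiinae	MC09	6	1009
Paralimnophyes sp.1	Orthocladiinae	LE09	2	69
Paralimnophyes sp.1	Orthocladiinae	ME09	2	27
Paralimnophyes sp.1	Orthocladiinae	UK09	0	2
Paratrichocladius sp.1	Orthocladiinae	HW09	1	6
Paratrichocladius sp.2	Orthocladiinae	SK09	1	211
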