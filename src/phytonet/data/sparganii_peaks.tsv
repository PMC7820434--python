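peak_id	rt_min	observed_mz	polarity	known_formula	reported_ppm	consistent	compound_name
SL1	0.55	104.1072	positive	C5H13NO	2.0	1	Choline
SL2	0.57	175.1184	positive	C6H14N4O2	-3.2	1	Arginine
SL3	0.62	138.0545	positive	C7H7NO2	-3.4	0	Trigonelline
SL4	0.86	136.0617	positive	C5H5N5	-2.7	0	Adenine
SL5	0.86	124.0394	positive	C6H5NO2	-2.5	0	Nicotinic acid
SL6	1.27	113.0346	positive	C4H4N2O2	-3.1	0	Uracil
SL7	1.35	117.0195	negative	C4H6O4	1.4	1	Succinic acid
SL8	1.65	182.0812	positive	C9H11NO3	0.2	1	Tyrosine
SL9	1.62	132.1015	positive	C6H13NO2	-3.1	1	D-Tert-Leucine
SL10	2.13	268.1038	positive	C10H13N5O4	-1.2	0	Adenine nucleoside
SL11	4.14	167.0352	negative	C8H8O4	1.3	1	Vanillic acid
SL12	4.19	166.0853	positive	C9H11NO2	-1.5	0	Phenylalanine
SL13	6.07	137.0249	negative	C7H6O3	3.5	1	4-Hydroxybenzoic acid
SL14	7.37	227.1028	negative	C10H14N2O5	0.7	0	Carbidopa
SL15	9.76	179.0349	negative	C9H8O4	5.7	0	Caffeic acid
SL16	10.02	123.0439	positive	C7H6O2	-1.3	1	Benzoic acid
SL17	10.44	253.0716	negative	C12H14O6	-0.6	1	Hwanggeumchal B
SL18	12.88	445.1336	negative	C19H26O12	-3.5	1	4-hydroxy-2-methoxyphenyl glucopyranoside derivative
SL19	13.57	253.0716	negative	C12H14O6	-0.6	1	1-Caffeoylglycerol
SL20	13.69	237.0764	negative	C12H14O5	-1.9	1	3-(4-hydroxyphenyl)-2-propenoic acid dihydroxypropyl ester
SL21	15.55	163.0404	negative	C9H8O3	2.0	1	4-Coumaric acid
SL22	17.72	237.0768	negative	C12H14O5	-0.2	1	1-O-p-coumaroylglycerol
SL23	17.74	193.0505	negative	C10H10O4	5.0	0	Ferulic acid
SL24	20.88	267.0873	negative	C13H16O6	-0.4	1	3-(4-hydroxy-3-methoxyphenyl)-2-propenoic acid dihydroxypropyl ester
SL25	21.11	267.0875	negative	C13H16O6	0.3	1	1-O-Trans-Feruloylglycerol
SL26	24.37	219.0661	negative	C12H12O4	4.2	0	Decarboxy-citrinone
SL27	29.2	609.1450	negative	C27H30O16	-1.8	1	Rutin
SL28	29.26	447.1279	positive	C22H22O10	-1.5	1	Tilianin
SL29	29.55	261.1337	negative	C12H22O6	-2.5	1	9-(2',3'-Dihydroxypropyloxy)-9-oxononanoic acid
SL30	30.18	187.0980	negative	C9H16O4	2.2	1	Azelaic acid
SL31	32.53	623.1621	negative	C28H32O16	0.5	1	Narcissin
SL32	35.33	381.1180	positive	C18H20O9	0.0	1	4-methylumbelliferyl glucuronide ethyl ester
SL33	35.66	283.0612	negative	C16H12O5	0.0	1	Acacetin
SL34	35.75	429.1168	negative	C22H22O9	-2.8	0	Feruloyl-caffeoylglycerol
SL35	37.29	413.1224	negative	C22H22O8	-4.3	1	p-Coumaroyl-feruloylglycerol
SL36	37.42	381.1131	negative	C21H20O7	1.5	0	1,3-O-Di-trans-p-coumaroylglycerol
SL37	37.43	443.1324	negative	C23H24O9	-5.3	1	1,3-O-Diferuloyl glycerol
SL38	37.45	413.1226	negative	C22H22O8	-1.2	0	1-O-Feruloyl-3-O-p-coumaroylglycerol
SL39	38.88	283.0605	negative	C16H12O5	-2.5	1	Methyl 3,6-dihydroxy-2-[(2-hydroxyphenyl)ethynyl]benzoate
SL40	40.359	327.21714	positive	C18H31O5	1.6	0	9S,12R,13S-Trihydroxy-10E,15Z-octadecadienoic acid
SL41	41.74	329.2320	negative	C18H34O5	-4.1	1	Sanleng acid
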