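haplotype	4	7	9	10	14	16	37	46	54	79	85	88	99	100	111	115	118	121	131	148	169	175	190	193	197	200	208	209	245	247	268	277	287	289	292	295	308	310	322	331	355	361	364	382	385	388	391	400	406	417	418	429	frequency	fragments	group
H1	T	A	T	A	A	T	C	G	T	A	A	G	T	A	T	A	G	T	G	A	T	G	A	T	T	A	T	A	G	A	C	T	G	C	T	T	T	G	G	C	C	T	C	A	G	A	G	T	T	T	T	G	0.284	451	group1
H2	.	.	.	.	T	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	0.042	451	group1
H3	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	.	.	.	0.048	451	group1
H4	.	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	.	.	.	0.061	451	group1
H5	.	.	.	.	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	.	.	A	.	.	.	.	.	.	.	0.042	451	group1
H6	.	.	.	.	.	.	G	.	.	.	.	A	.	.	.	.	A	.	.	.	A	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	.	.	.	T	C	.	.	.	.	0.015	451	group1
H7	.	.	.	.	.	.	G	.	.	.	.	A	.	.	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	.	.	.	T	C	.	.	.	.	0.081	451	group1
H34	.	.	.	.	T	.	G	.	.	.	.	A	.	.	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	.	.	.	T	C	.	.	.	.	0.004	451	group1
H35	.	.	.	.	.	.	G	.	.	.	.	A	.	.	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	.	.	.	A	C	.	.	.	.	0.004	451	group1
H36	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	.	.	.	0.009	451	group1
H37	.	.	.	T	T	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	0.006	451	group1
H38	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	A	.	.	0.004	451	group1
H39	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	0.006	451	group1
HU40	.	.	.	.	C	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	0.002	451	group1
HU41	.	.	.	.	T	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	0.002	451	group1
HU42	.	.	C	T	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	0.002	451	group1
HU43	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	A	0.002	451	group1
HU44	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	.	0.002	261,451	group1
HU45	.	.	.	.	.	.	.	.	.	G	.	.	.	.	.	.	.	.	A	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	.	.	A	.	.	.	.	.	.	.	0.002	451	group1
HU46	.	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	.	.	A	.	.	.	.	.	.	.	0.002	451	group1
HU47	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	.	.	C	C	A	.	.	.	.	T	.	A	.	A	C	.	.	.	.	0.002	261,451	group1
HU48	G	.	.	.	.	.	G	.	.	.	.	A	.	.	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	.	.	.	T	C	.	.	.	.	0.002	261,451	group1
HU49	.	.	.	.	.	.	.	.	.	.	.	A	.	.	.	.	A	.	.	G	.	.	G	.	.	.	C	.	.	.	.	.	.	T	.	C	C	.	A	T	T	.	T	.	.	.	A	C	.	.	.	.	0.002	451	group1
H8	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	.	A	.	.	.	.	A	G	.	.	.	.	T	C	.	.	.	.	T	.	C	C	A	A	.	.	C	T	G	.	.	A	C	C	.	C	.	0.051	261,451	group2
H9	.	.	.	.	.	.	.	.	.	.	G	A	.	G	.	.	A	.	.	.	.	A	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	A	A	.	.	C	T	G	.	.	A	C	C	.	C	.	0.024	261	group2
H10	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	.	A	.	.	.	.	A	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	A	A	.	.	C	T	G	.	.	A	C	C	.	C	.	0.046	261,451	group2
H11	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	.	A	.	.	.	.	A	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	.	C	T	G	.	.	A	C	C	.	C	.	0.009	261,451	group2
H12	.	.	.	.	.	.	.	A	.	.	.	A	.	G	.	.	A	.	.	.	.	A	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	.	C	T	G	.	.	A	C	.	.	C	.	0.006	261,451	group2
H13	.	.	.	.	.	.	.	A	.	.	.	A	.	G	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	.	C	T	G	.	.	A	C	.	.	C	.	0.013	261,451	group2
H14	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	.	C	T	G	.	.	A	C	.	.	C	.	0.007	261	group2
H15	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	G	A	.	.	.	.	.	G	.	.	G	.	.	.	.	.	.	.	G	A	C	C	.	A	.	.	C	T	G	.	.	A	C	.	.	C	.	0.004	261	group2
H16	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	C	T	G	.	.	A	C	.	.	C	.	0.004	261,451	group2
H17	.	.	.	.	.	.	.	A	.	.	.	A	.	G	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	.	.	T	G	.	.	A	C	.	.	C	.	0.004	261,451	group2
H18	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	G	A	.	.	.	A	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	G	.	.	A	C	.	.	.	.	0.026	261	group2
H19	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	.	A	.	.	.	A	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	G	.	.	A	C	.	.	.	.	0.02	261,451	group2
H20	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	.	A	A	.	.	A	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	G	.	.	A	C	.	.	.	.	0.004	261,451	group2
H21	.	.	.	.	.	.	.	.	.	.	.	A	A	G	C	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	G	.	.	A	C	.	.	.	.	0.004	261,451	group2
H22	.	.	.	.	.	.	.	.	.	.	.	A	A	G	.	.	A	A	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	G	.	.	A	C	.	.	.	.	0.006	261,451	group2
H23	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	G	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	G	.	.	A	C	.	.	.	.	0.026	261	group2
H24	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	G	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	G	.	.	A	C	C	.	.	.	0.004	261	group2
H25	.	.	.	.	.	.	.	A	.	.	.	A	.	G	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	G	.	.	A	C	.	.	.	.	0.015	261,451	group2
H26	.	.	.	.	T	.	.	A	.	.	.	A	.	G	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	G	.	.	A	C	.	.	.	.	0.007	261,451	group2
H27	.	.	.	.	T	.	.	.	.	.	.	A	.	G	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	G	.	.	A	C	.	.	.	.	0.004	261,451	group2
H28	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	G	.	.	A	C	.	.	.	.	0.061	261,451	group2
H29	.	.	.	T	.	.	.	.	.	.	.	A	.	G	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	G	.	.	A	C	.	.	.	.	0.006	261,451	group2
H30	.	G	.	.	.	.	.	.	.	.	.	A	.	G	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	G	.	.	T	.	C	C	.	A	.	T	.	T	G	.	G	A	C	.	.	.	.	0.004	261,451	group2
H31	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	G	.	T	.	C	C	.	A	.	T	.	T	G	.	.	A	C	.	.	.	.	0.004	261,451	group2
H32	.	.	.	.	.	.	.	.	.	.	G	A	.	G	.	.	A	.	.	C	.	A	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	A	A	.	.	C	T	G	.	.	A	C	C	.	C	.	0.004	261,451	group2
H33	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	.	A	.	.	.	.	A	G	.	.	.	.	T	.	.	.	.	.	T	.	C	C	A	A	.	.	C	T	G	.	.	A	C	C	.	C	.	0.004	261,451	group2
HU50	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	G	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	.	C	T	G	.	.	A	C	.	.	C	.	0.002	261	group2
HU51	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	.	C	T	G	.	.	A	C	.	.	.	.	0.002	261,451	group2
HU52	.	.	.	.	.	.	.	.	.	.	.	A	.	G	.	G	A	.	.	.	A	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	.	.	.	A	C	.	.	.	.	0.002	261,451	group2
HU53	.	.	.	.	T	.	.	.	.	.	.	A	.	G	.	.	A	.	.	.	A	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	G	.	.	A	C	.	.	.	.	0.002	261	group2
HU54	.	.	.	.	.	.	.	.	.	.	.	A	A	G	.	.	A	.	.	.	A	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	G	.	.	A	C	.	.	.	.	0.002	261,451	group2
HU55	.	.	.	.	.	.	.	.	G	.	.	A	.	G	.	G	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	T	.	T	G	.	.	A	C	.	.	.	.	0.002	261	group2
HU56	.	.	.	.	.	.	.	.	G	.	.	A	.	G	.	G	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	.	A	.	.	.	T	G	.	.	A	C	.	.	.	.	0.002	261	group2
HU57	.	.	.	.	.	C	.	.	.	.	.	A	.	G	.	.	A	.	.	.	.	.	G	.	.	.	.	.	.	.	.	.	.	T	.	C	C	A	A	.	T	.	T	G	.	.	A	C	.	.	.	.	0.002	261	group2
HU58	.	.	.	.	.	.	A	.	.	.	.	A	.	.	.	.	A	.	.	.	.	.	.	A	C	.	.	.	.	.	.	.	.	A	.	.	.	.	.	.	T	.	T	.	.	.	.	.	.	.	.	.	0.002	none	ungrouped
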