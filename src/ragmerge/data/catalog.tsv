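rag_index	order	edges	lambda2	color	source
2.1	2	0-1	2.00000	red	default
3.1	3	0-1;1-2	1.00000	red	default
4.1	4	0-1;0-2;1-3	0.58579	red	default
4.2	4	0-1;1-2;1-3	1.00000	red	default
5.1	5	0-1;0-2;1-3;3-4	0.38197	red	default
5.2	5	0-1;0-2;1-3;1-4	0.51881	red	default
5.3	5	0-1;1-2;1-3;1-4	1.00000	red	default
6.1	6	0-1;0-2;1-4;2-3;4-5	0.26795	red	default
6.2	6	0-1;0-2;0-3;1-4;4-5	0.32487	red	paper
6.3	6	0-1;0-2;1-3;1-5;3-4	0.38197	red	default
6.4	6	0-1;0-2;0-3;1-4;1-5	0.43845	blue	paper
6.5	6	0-1;0-2;1-3;1-4;1-5	0.48586	black	paper
6.6	6	0-1;1-2;1-3;1-4;1-5	1.00000	red	paper
7.1	7	0-1;0-2;1-4;2-3;4-5;5-6	0.19806	red	paper
7.2	7	0-1;0-2;1-4;2-3;4-5;4-6	0.22538	red	paper
7.3	7	0-1;0-2;1-4;1-6;2-3;4-5	0.26032	red	paper
7.4	7	0-1;0-2;0-3;1-4;4-5;4-6	0.26795	blue	default
7.5	7	0-1;0-2;0-3;0-4;1-5;5-6	0.29553	blue	default
7.6	7	0-1;0-2;0-3;1-4;1-6;4-5	0.32172	red	paper
7.7	7	0-1;0-2;1-3;1-5;3-4;5-6	0.38197	blue	default
7.8	7	0-1;0-2;1-3;1-5;1-6;3-4	0.38197	blue	default
7.9	7	0-1;0-2;0-3;1-4;1-5;1-6	0.39832	black	paper
7.10	7	0-1;0-2;1-3;1-4;1-5;1-6	0.46593	black	paper
7.11	7	0-1;1-2;1-3;1-4;1-5;1-6	1.00000	black	paper
8.1	8	0-1;0-2;1-5;2-3;3-4;5-6;6-7	0.15224	blue	default
8.2	8	0-1;0-2;1-5;2-3;2-4;5-6;6-7	0.16672	blue	default
8.3	8	0-1;0-2;0-4;1-5;2-3;5-6;6-7	0.18639	red	paper
8.4	8	0-1;0-2;1-5;2-3;2-4;5-6;5-7	0.18639	blue	default
8.5	8	0-1;0-2;1-4;1-7;2-3;4-5;5-6	0.19806	red	paper
8.6	8	0-1;0-2;1-4;2-3;4-5;4-6;4-7	0.20226	blue	default
8.7	8	0-1;0-2;0-4;1-5;2-3;5-6;5-7	0.21368	red	paper
8.8	8	0-1;0-2;1-4;1-7;2-3;4-5;4-6	0.22429	blue	default
8.9	8	0-1;0-2;0-3;0-4;1-5;5-6;5-7	0.23844	black	paper
8.10	8	0-1;0-2;1-4;1-6;2-3;4-5;6-7	0.24340	red	paper
8.11	8	0-1;0-2;0-4;1-5;1-7;2-3;5-6	0.25088	red	paper
8.12	8	0-1;0-2;1-4;1-6;1-7;2-3;4-5	0.25379	blue	default
8.13	8	0-1;0-2;0-3;1-4;1-7;4-5;4-6	0.26795	blue	default
8.14	8	0-1;0-2;0-3;0-4;0-5;1-6;6-7	0.27741	black	paper
8.15	8	0-1;0-2;0-3;0-4;1-5;1-7;5-6	0.28880	red	paper
8.16	8	0-1;0-2;0-3;1-4;1-6;4-5;6-7	0.30647	blue	default
8.17	8	0-1;0-2;0-3;1-4;1-6;1-7;4-5	0.31867	black	paper
8.18	8	0-1;0-2;0-3;0-4;1-5;1-6;1-7	0.35425	black	paper
8.19	8	0-1;0-2;0-3;1-4;1-5;1-6;1-7	0.37380	black	paper
8.20	8	0-1;0-2;1-3;1-5;1-7;3-4;5-6	0.38197	red	paper
8.21	8	0-1;0-2;1-3;1-5;1-6;1-7;3-4	0.38197	black	paper
8.22	8	0-1;0-2;1-3;1-4;1-5;1-6;1-7	0.45249	black	paper
8.23	8	0-1;1-2;1-3;1-4;1-5;1-6;1-7	1.00000	black	paper
9.1	9	0-1;0-2;1-5;2-3;3-4;5-6;6-7;7-8	0.12061	unknown	default
9.2	9	0-1;0-2;1-5;2-3;3-4;5-6;6-7;6-8	0.12888	unknown	default
9.3	9	0-1;0-2;1-5;2-3;2-4;5-6;6-7;6-8	0.13919	unknown	default
9.4	9	0-1;0-2;1-5;2-3;3-4;5-6;5-8;6-7	0.14042	unknown	default
9.5	9	0-1;0-2;1-6;2-3;2-4;2-5;6-7;7-8	0.14874	unknown	default
9.6	9	0-1;0-2;1-5;1-8;2-3;3-4;5-6;6-7	0.15057	red	paper
9.7	9	0-1;0-2;1-5;2-3;2-4;5-6;5-8;6-7	0.15381	unknown	default
9.8	9	0-1;0-2;0-5;1-6;2-3;2-4;6-7;7-8	0.16269	unknown	default
9.9	9	0-1;0-2;1-5;2-3;2-4;5-6;5-7;5-8	0.16492	unknown	default
9.10	9	0-1;0-2;1-5;1-8;2-3;2-4;5-6;6-7	0.16576	unknown	default
9.11	9	0-1;0-2;0-4;1-6;2-3;4-5;6-7;7-8	0.17084	red	paper
9.12	9	0-1;0-2;0-4;1-5;2-3;5-6;5-8;6-7	0.17291	unknown	default
9.13	9	0-1;0-2;0-4;0-5;1-6;2-3;6-7;7-8	0.17742	red	paper
9.14	9	0-1;0-2;1-5;1-8;2-3;2-4;5-6;5-7	0.18304	unknown	default
9.15	9	0-1;0-2;0-4;1-5;1-8;2-3;5-6;6-7	0.18623	unknown	default
9.16	9	0-1;0-2;1-4;2-3;4-5;4-6;4-7;4-8	0.18760	unknown	default
9.17	9	0-1;0-2;0-4;1-5;2-3;5-6;5-7;5-8	0.18836	unknown	default
9.18	9	0-1;0-2;1-5;1-7;2-3;2-4;5-6;7-8	0.19529	unknown	default
9.19	9	0-1;0-2;1-4;1-7;2-3;4-5;5-6;7-8	0.19806	unknown	default
9.20	9	0-1;0-2;1-4;1-7;1-8;2-3;4-5;5-6	0.19806	unknown	default
9.21	9	0-1;0-2;1-4;1-8;2-3;4-5;4-6;4-7	0.20223	unknown	default
9.22	9	0-1;0-2;1-5;1-7;1-8;2-3;2-4;5-6	0.20426	unknown	default
9.23	9	0-1;0-2;0-3;0-4;1-5;5-6;5-7;5-8	0.20871	unknown	default
9.24	9	0-1;0-2;0-4;1-5;1-8;2-3;5-6;5-7	0.21179	unknown	default
9.25	9	0-1;0-2;0-3;0-4;0-5;1-6;6-7;6-8	0.22013	unknown	default
9.26	9	0-1;0-2;1-4;1-7;2-3;4-5;4-6;7-8	0.22165	unknown	default
9.27	9	0-1;0-2;1-4;1-7;1-8;2-3;4-5;4-6	0.22324	red	paper
9.28	9	0-1;0-2;0-4;1-5;1-7;2-3;5-6;7-8	0.23107	unknown	default
9.29	9	0-1;0-2;0-3;0-4;1-5;1-8;5-6;5-7	0.23773	unknown	default
9.30	9	0-1;0-2;1-4;1-6;1-8;2-3;4-5;6-7	0.23976	unknown	default
9.31	9	0-1;0-2;0-4;1-5;1-7;1-8;2-3;5-6	0.24270	unknown	default
9.32	9	0-1;0-2;1-4;1-6;1-7;1-8;2-3;4-5	0.24825	unknown	default
9.33	9	0-1;0-2;0-3;0-4;0-5;0-6;1-7;7-8	0.26503	unknown	default
9.34	9	0-1;0-2;0-3;1-4;1-7;4-5;4-6;7-8	0.26795	unknown	default
9.35	9	0-1;0-2;0-3;0-4;1-5;1-7;5-6;7-8	0.26795	unknown	default
9.36	9	0-1;0-2;0-3;1-4;1-7;1-8;4-5;4-6	0.26795	unknown	default
9.37	9	0-1;0-2;0-3;0-4;0-5;1-6;1-8;6-7	0.26795	unknown	default
9.38	9	0-1;0-2;0-3;0-4;1-5;1-7;1-8;5-6	0.28247	unknown	default
9.39	9	0-1;0-2;0-3;1-4;1-6;1-8;4-5;6-7	0.30469	unknown	default
9.40	9	0-1;0-2;0-3;1-4;1-6;1-7;1-8;4-5	0.31576	unknown	default
9.41	9	0-1;0-2;0-3;0-4;1-5;1-6;1-7;1-8	0.32718	unknown	default
9.42	9	0-1;0-2;0-3;1-4;1-5;1-6;1-7;1-8	0.35716	unknown	default
9.43	9	0-1;0-2;1-3;1-5;1-7;3-4;5-6;7-8	0.38197	unknown	default
9.44	9	0-1;0-2;1-3;1-5;1-7;1-8;3-4;5-6	0.38197	unknown	default
9.45	9	0-1;0-2;1-3;1-5;1-6;1-7;1-8;3-4	0.38197	unknown	default
9.46	9	0-1;0-2;1-3;1-4;1-5;1-6;1-7;1-8	0.44280	unknown	default
9.47	9	0-1;1-2;1-3;1-4;1-5;1-6;1-7;1-8	1.00000	unknown	default
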