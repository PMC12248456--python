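decile	mean_risk_score	lifetime_risk_per_1e5	relative_risk	mst_years
1	3.4	362	0.11	45.5
2	4.8	925	0.28	18.7
3	5.6	1576	0.47	10.8
4	6.3	2360	0.71	6.9
5	6.9	3348	1.00	4.5
6	7.5	4753	1.42	3.1
7	8.2	6698	2.00	2.0
8	8.9	9551	2.85	1.3
9	9.9	13239	4.25	0.7
10	11.8	24523	7.33	0.1
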