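# Spawning performance of the 16 females whose eggs entered the proteomic
# experiments: egg counts and cumulative percent embryo survival at 8, 24,
# 48 and 72 hours post spawning (hps), with the percentage of surviving
# embryos that were abnormal at each time point (abn_* columns).
female_id	experiment	eggs_total	eggs_incubated	pct_intact_2_3hps	surv_8	abn_8	surv_24	abn_24	surv_48	abn_48	surv_72	abn_72
1	pooled	115	60	100	100	1.7	98.3	0	98.3	0	98.3	0
2	pooled	216	60	100	100	0	100	0	100	0	100	0
3	pooled	355	60	100	100	0	100	0	100	0	100	0
4	pooled	401	60	100	100	0	100	0	100	0	100	0
5	pooled	129	60	96.7	91.7	96.4	3.3	0	3.3	0	3.3	0
6	pooled	224	60	100	0	0	0	0	0	0	0	0
7	pooled	165	53	100	79.2	76.2	11.3	0	11.3	0	11.3	0
8	pooled	266	63	100	17.5	0	14.3	0	14.3	0	14.3	0
9	multiple	401	60	100	100	0	100	0	100	0	100	0
10	multiple	355	60	100	100	0	100	0	100	0	100	0
11	multiple	216	60	100	100	0	100	0	100	0	100	0
12	multiple	124	60	100	100	0	100	0	100	0	100	0
13	multiple	251	60	100	0	0	0	0	0	0	0	0
14	multiple	187	60	100	13.3	0	11.7	0	11.7	0	11.7	0
15	multiple	481	60	100	6.7	0	6.7	0	6.7	0	6.7	0
16	multiple	404	61	96.7	85.2	67.3	16.4	0	16.4	0	16.4	0
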