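patient_id	sex	age_months	bmi	bmi_percentile	wfh_zscore	weight_status_note
P1	F	60	NA	NA	NA	referred_obese
P2	F	408	59.1	NA	NA	measured
P3	F	168	26.8	93.3	NA	measured
P4	F	72	19.7	96.8	NA	measured
P5	M	132	30.8	99	NA	measured
P6	F	180	37.1	99.1	NA	measured
P7	F	96	33.2	99.7	NA	measured
P8	M	72	28.8	99.9	NA	measured
P9	F	84	22.6	98.2	NA	measured
P10	F	96	29.1	99.5	NA	measured
P11	M	252	NA	NA	NA	referred_obese
P12	M	120	29.8	99	NA	measured
P13	F	108	24.7	98.2	NA	measured
P14	F	60	24.0	99.7	NA	measured
P15	M	120	31.0	99.3	NA	measured
P16	F	180	40.5	99.4	NA	measured
P17	M	72	30.6	99.9	NA	measured
P18	M	72	33.4	99.9	NA	measured
P19	M	72	25.8	99.8	NA	measured
P20	F	132	26.7	97.6	NA	measured
P21	F	12	NA	NA	1.0	measured
P22	M	204	28.7	95.7	NA	measured
P23	F	108	31.1	99.5	NA	measured
P24	M	168	28.7	97.6	NA	measured
P25	M	96	25.4	99.2	NA	measured
P26	F	120	22.1	93.4	NA	measured
P27	F	48	NA	NA	NA	hyperphagia_only
P28	F	84	20.5	96.6	NA	measured
P29	M	144	30.4	98.8	NA	measured
P30	M	96	NA	NA	NA	referred_obese
P31	M	132	42.2	99.7	NA	measured
P32	M	72	31.2	99.9	NA	measured
P33	F	84	21.9	97.9	NA	measured
P34	F	96	25.9	98.9	NA	measured
P35	M	120	28.1	99	NA	measured
P36	M	108	22.2	96.8	NA	measured
P37	F	96	22.3	97.4	NA	measured
P38	F	216	41.5	99	NA	measured
P39	F	96	NA	NA	NA	referred_obese
P40	M	36	34.7	99.9	NA	measured
P41	M	108	32.5	99.6	NA	measured
P42	M	13	NA	NA	1.0	measured
P43	M	216	NA	NA	NA	referred_obese
P44	M	60	27.9	99.9	NA	measured
P45	F	84	24.8	98.9	NA	measured
P46	F	24	17.7	85	NA	measured
P47	M	180	39.5	99.6	NA	measured
P48	M	24	24.4	99.9	NA	measured
P49	F	168	NA	NA	NA	referred_obese
P50	M	120	30.4	99.3	NA	measured
P51	F	168	27.9	95.8	NA	measured
P52	F	24	27.0	99.9	NA	measured
P53	F	5	NA	NA	NA	referred_obese
P54	F	108	34.3	99.7	NA	measured
P55	F	84	23.6	98.8	NA	measured
P56	F	156	36.8	99.4	NA	measured
P57	M	180	43.1	99.7	NA	measured
P58	M	48	22.0	99.9	NA	measured
P59	F	192	38.5	99	NA	measured
P60	F	84	24.8	99.3	NA	measured
P61	M	168	37.0	99.5	NA	measured
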