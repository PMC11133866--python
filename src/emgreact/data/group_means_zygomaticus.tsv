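condition	bin	time_ms	mean	sd
no_regulation	1	500	137.1	121.2
no_regulation	2	1000	128.3	111.0
no_regulation	3	1500	132.1	116.0
no_regulation	4	2000	137.5	138.4
no_regulation	5	2500	136.4	132.6
no_regulation	6	3000	134.4	124.1
no_regulation	7	3500	133.8	118.8
no_regulation	8	4000	133.7	125.7
no_regulation	9	4500	133.1	121.5
no_regulation	10	5000	132.7	126.7
no_regulation	11	5500	132.2	127.5
no_regulation	12	6000	128.7	125.3
no_regulation	13	6500	129.7	128.4
no_regulation	14	7000	128.3	117.7
no_regulation	15	7500	126.6	111.3
no_regulation	16	8000	131.6	114.1
neutralize	1	500	129.9	122.0
neutralize	2	1000	116.3	94.3
neutralize	3	1500	112.1	86.1
neutralize	4	2000	109.2	69.8
neutralize	5	2500	104.2	51.2
neutralize	6	3000	102.2	47.8
neutralize	7	3500	101.5	47.9
neutralize	8	4000	102.5	63.4
neutralize	9	4500	99.4	39.9
neutralize	10	5000	98.3	41.3
neutralize	11	5500	100.3	70.6
neutralize	12	6000	98.7	50.5
neutralize	13	6500	96.8	42.1
neutralize	14	7000	96.0	34.2
neutralize	15	7500	96.2	35.6
neutralize	16	8000	103.1	41.4
transform	1	500	133.5	129.8
transform	2	1000	118.2	92.9
transform	3	1500	109.9	65.1
transform	4	2000	108.0	59.8
transform	5	2500	105.9	77.9
transform	6	3000	102.4	51.9
transform	7	3500	100.2	40.5
transform	8	4000	99.9	42.4
transform	9	4500	99.0	40.5
transform	10	5000	101.2	56.0
transform	11	5500	99.5	39.8
transform	12	6000	98.2	37.9
transform	13	6500	98.2	41.2
transform	14	7000	98.2	40.5
transform	15	7500	97.6	39.3
transform	16	8000	104.7	42.8
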