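condition	bin	time_ms	mean	sd
no_regulation	1	500	111.3	61.3
no_regulation	2	1000	97.3	50.2
no_regulation	3	1500	95.2	51.6
no_regulation	4	2000	95.3	50.6
no_regulation	5	2500	93.9	49.5
no_regulation	6	3000	94.2	49.6
no_regulation	7	3500	94.1	49.1
no_regulation	8	4000	94.2	49.1
no_regulation	9	4500	94.7	49.8
no_regulation	10	5000	95.2	52.6
no_regulation	11	5500	95.6	51.5
no_regulation	12	6000	95.8	56.0
no_regulation	13	6500	96.7	60.1
no_regulation	14	7000	97.9	66.6
no_regulation	15	7500	98.7	69.6
no_regulation	16	8000	107.4	82.7
neutralize	1	500	111.5	60.9
neutralize	2	1000	100.4	60.1
neutralize	3	1500	100.4	58.7
neutralize	4	2000	99.7	51.4
neutralize	5	2500	100.0	50.1
neutralize	6	3000	100.2	50.4
neutralize	7	3500	101.3	56.7
neutralize	8	4000	100.2	50.4
neutralize	9	4500	100.1	49.8
neutralize	10	5000	100.0	51.8
neutralize	11	5500	100.0	45.8
neutralize	12	6000	101.2	54.2
neutralize	13	6500	102.4	58.6
neutralize	14	7000	101.7	48.9
neutralize	15	7500	102.0	47.3
neutralize	16	8000	109.9	49.0
transform	1	500	112.4	55.4
transform	2	1000	101.6	50.4
transform	3	1500	106.5	96.8
transform	4	2000	106.9	78.6
transform	5	2500	107.7	56.9
transform	6	3000	109.6	59.3
transform	7	3500	111.6	68.9
transform	8	4000	112.3	65.8
transform	9	4500	113.5	68.6
transform	10	5000	117.1	88.7
transform	11	5500	119.0	91.5
transform	12	6000	119.6	83.0
transform	13	6500	120.3	77.5
transform	14	7000	120.8	78.2
transform	15	7500	123.4	80.0
transform	16	8000	131.3	79.1
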