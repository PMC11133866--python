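muscle	cond_a	cond_b	bin	time_ms	d
corrugator	neutralize	no_regulation	1	500	0.01
corrugator	neutralize	no_regulation	2	1000	0.15
corrugator	neutralize	no_regulation	3	1500	0.23
corrugator	neutralize	no_regulation	4	2000	0.24
corrugator	neutralize	no_regulation	5	2500	0.33
corrugator	neutralize	no_regulation	6	3000	0.32
corrugator	neutralize	no_regulation	7	3500	0.37
corrugator	neutralize	no_regulation	8	4000	0.3
corrugator	neutralize	no_regulation	9	4500	0.28
corrugator	neutralize	no_regulation	10	5000	0.24
corrugator	neutralize	no_regulation	11	5500	0.23
corrugator	neutralize	no_regulation	12	6000	0.25
corrugator	neutralize	no_regulation	13	6500	0.25
corrugator	neutralize	no_regulation	14	7000	0.17
corrugator	neutralize	no_regulation	15	7500	0.14
corrugator	neutralize	no_regulation	16	8000	0.08
corrugator	transform	no_regulation	1	500	0.04
corrugator	transform	no_regulation	2	1000	0.23
corrugator	transform	no_regulation	3	1500	0.39
corrugator	transform	no_regulation	4	2000	0.45
corrugator	transform	no_regulation	5	2500	0.67
corrugator	transform	no_regulation	6	3000	0.73
corrugator	transform	no_regulation	7	3500	0.75
corrugator	transform	no_regulation	8	4000	0.75
corrugator	transform	no_regulation	9	4500	0.76
corrugator	transform	no_regulation	10	5000	0.72
corrugator	transform	no_regulation	11	5500	0.75
corrugator	transform	no_regulation	12	6000	0.75
corrugator	transform	no_regulation	13	6500	0.77
corrugator	transform	no_regulation	14	7000	0.71
corrugator	transform	no_regulation	15	7500	0.74
corrugator	transform	no_regulation	16	8000	0.64
corrugator	transform	neutralize	1	500	0.03
corrugator	transform	neutralize	2	1000	0.06
corrugator	transform	neutralize	3	1500	0.22
corrugator	transform	neutralize	4	2000	0.27
corrugator	transform	neutralize	5	2500	0.36
corrugator	transform	neutralize	6	3000	0.43
corrugator	transform	neutralize	7	3500	0.42
corrugator	transform	neutralize	8	4000	0.5
corrugator	transform	neutralize	9	4500	0.54
corrugator	transform	neutralize	10	5000	0.55
corrugator	transform	neutralize	11	5500	0.61
corrugator	transform	neutralize	12	6000	0.57
corrugator	transform	neutralize	13	6500	0.59
corrugator	transform	neutralize	14	7000	0.64
corrugator	transform	neutralize	15	7500	0.69
corrugator	transform	neutralize	16	8000	0.64
zygomaticus	neutralize	no_regulation	1	500	-0.11
zygomaticus	neutralize	no_regulation	2	1000	-0.21
zygomaticus	neutralize	no_regulation	3	1500	-0.36
zygomaticus	neutralize	no_regulation	4	2000	-0.44
zygomaticus	neutralize	no_regulation	5	2500	-0.52
zygomaticus	neutralize	no_regulation	6	3000	-0.53
zygomaticus	neutralize	no_regulation	7	3500	-0.61
zygomaticus	neutralize	no_regulation	8	4000	-0.57
zygomaticus	neutralize	no_regulation	9	4500	-0.63
zygomaticus	neutralize	no_regulation	10	5000	-0.63
zygomaticus	neutralize	no_regulation	11	5500	-0.61
zygomaticus	neutralize	no_regulation	12	6000	-0.58
zygomaticus	neutralize	no_regulation	13	6500	-0.66
zygomaticus	neutralize	no_regulation	14	7000	-0.71
zygomaticus	neutralize	no_regulation	15	7500	-0.71
zygomaticus	neutralize	no_regulation	16	8000	-0.66
zygomaticus	transform	no_regulation	1	500	-0.06
zygomaticus	transform	no_regulation	2	1000	-0.18
zygomaticus	transform	no_regulation	3	1500	-0.4
zygomaticus	transform	no_regulation	4	2000	-0.47
zygomaticus	transform	no_regulation	5	2500	-0.53
zygomaticus	transform	no_regulation	6	3000	-0.55
zygomaticus	transform	no_regulation	7	3500	-0.58
zygomaticus	transform	no_regulation	8	4000	-0.58
zygomaticus	transform	no_regulation	9	4500	-0.64
zygomaticus	transform	no_regulation	10	5000	-0.57
zygomaticus	transform	no_regulation	11	5500	-0.63
zygomaticus	transform	no_regulation	12	6000	-0.56
zygomaticus	transform	no_regulation	13	6500	-0.61
zygomaticus	transform	no_regulation	14	7000	-0.64
zygomaticus	transform	no_regulation	15	7500	-0.64
zygomaticus	transform	no_regulation	16	8000	-0.58
zygomaticus	transform	neutralize	1	500	0.05
zygomaticus	transform	neutralize	2	1000	0.04
zygomaticus	transform	neutralize	3	1500	-0.06
zygomaticus	transform	neutralize	4	2000	-0.05
zygomaticus	transform	neutralize	5	2500	0.06
zygomaticus	transform	neutralize	6	3000	0.01
zygomaticus	transform	neutralize	7	3500	-0.07
zygomaticus	transform	neutralize	8	4000	-0.11
zygomaticus	transform	neutralize	9	4500	-0.02
zygomaticus	transform	neutralize	10	5000	0.14
zygomaticus	transform	neutralize	11	5500	-0.03
zygomaticus	transform	neutralize	12	6000	-0.03
zygomaticus	transform	neutralize	13	6500	0.07
zygomaticus	transform	neutralize	14	7000	0.14
zygomaticus	transform	neutralize	15	7500	0.09
zygomaticus	transform	neutralize	16	8000	0.08
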