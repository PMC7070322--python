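impurity,concentration_level_pct,added_conc,found_conc,recovery_pct
EP impurity A,0.05,0.2548,0.2632,103.31
EP impurity A,0.40,2.0380,2.0309,99.65
EP impurity A,0.48,2.4456,2.4255,99.18
EP impurity B,0.05,0.2498,0.2378,95.23
EP impurity B,0.15,0.7493,0.7468,99.67
EP impurity B,0.18,0.8991,0.8850,98.43
USP related compound C,0.05,0.2551,0.2073,81.26
USP related compound C,0.15,0.7653,0.6920,90.42
USP related compound C,0.18,0.9184,0.8442,91.92
USP related compound D,0.05,0.2637,0.2484,94.21
USP related compound D,0.15,0.7911,0.7753,98.00
USP related compound D,0.18,0.9493,0.9546,100.56
USP o-celecoxib,0.05,0.2690,0.2699,100.32
USP o-celecoxib,0.15,0.8071,0.8128,100.71
USP o-celecoxib,0.18,0.9685,0.9794,101.12
USP desaryl celecoxib,0.05,0.2455,0.2449,99.79
USP desaryl celecoxib,0.15,0.7364,0.7375,100.16
USP desaryl celecoxib,0.18,0.8836,0.8785,99.42
USP 4-methylacetophenone,0.05,0.2356,0.2371,100.65
USP 4-methylacetophenone,0.15,0.7067,0.7066,99.98
USP 4-methylacetophenone,0.18,0.8481,0.8452,99.66
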