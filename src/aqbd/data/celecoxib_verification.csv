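run_id,acetonitrile,flow_rate,temperature,R1,R2,R3,RT
N6,46.5,0.75,40,2.47,3.37,3.69,29.67
N5,43.5,0.75,40,2.76,4.21,2.13,41.41
N10,45,0.8,38.5,2.57,3.7,2.97,33.77
N1,43.5,0.75,37,2.71,4.1,2.23,44.19
N4,46.5,0.85,37,2.38,3.25,3.66,27.84
N7,43.5,0.85,40,2.69,4.12,2.06,36.63
N11,45,0.8,38.5,2.56,3.69,2.95,33.64
N3,43.5,0.85,37,2.65,4.03,2.17,39.11
N8,46.5,0.85,40,2.41,3.3,3.59,26.21
N2,46.5,0.75,37,2.44,3.31,3.76,31.47
N9,45,0.8,38.5,2.58,3.71,2.97,33.82
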