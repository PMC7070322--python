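run_id,acetonitrile,flow_rate,temperature,R1,R2,R3,RT
N14,46,0.75,40,2.53,3.50,3.46,31.38
N17,46,0.75,35,2.45,3.37,3.55,34.56
N1,42,0.5,30,2.80,4.46,1.63,94.93
N10,50,0.75,35,2.11,2.25,4.72,23.16
N11,46,0.5,35,2.58,3.52,3.82,51.62
N5,42,0.5,40,3.04,4.84,1.18,75.61
N6,50,0.5,40,2.24,2.47,5.19,31.88
N12,46,1.0,35,2.31,3.21,3.29,26.04
N2,50,0.5,30,2.16,2.20,5.03,37.80
N15,46,0.75,35,2.47,3.37,3.59,34.70
N3,42,1.0,30,2.51,4.07,1.43,47.96
N4,50,1.0,30,1.89,1.80,4.02,18.96
N16,46,0.75,35,2.45,3.37,3.53,34.50
N13,46,0.75,30,2.32,3.20,3.49,37.98
N8,50,1.0,40,1.99,2.18,4.39,16.05
N7,42,1.0,40,2.76,4.46,1.04,38.41
N9,42,0.75,35,2.80,4.52,1.30,57.03
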