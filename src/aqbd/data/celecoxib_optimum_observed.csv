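response,predicted,observed
R1,2.59317,2.58367
R2,3.76787,3.73814
R3,2.89245,2.91747
RT,32.3846,32.648
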