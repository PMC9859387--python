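t,C_true,N_true
5,90880136.51,150047685.76
10,90657024.59,149681776.36
15,90507781.43,149437930.11
20,90408340.72,149275456.17
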