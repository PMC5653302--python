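scale,descriptor,explained_variance_pct,model_coefficient
coarse,PCNM13,0.28,0.19
coarse,PCNM29,0.74,-0.29
medium,PCNM58,0.30,0.19
medium,PCNM75,0.28,-0.19
medium,PCNM113,0.25,-0.18
medium,PCNM120,0.23,-0.17
medium,PCNM126,0.38,0.21
medium,PCNM128,0.19,0.16
medium,PCNM142,0.26,0.18
fine,PCNM188,0.47,-0.23
fine,PCNM211,0.25,0.18
fine,PCNM216,0.29,-0.19
fine,PCNM264,0.56,-0.25
fine,PCNM275,0.33,-0.20
fine,PCNM281,0.19,0.16
fine,PCNM296,0.22,-0.17
fine,PCNM305,0.26,-0.18
fine,PCNM316,0.27,-0.18
fine,PCNM319,0.43,-0.23
fine,PCNM327,0.46,-0.23
fine,PCNM359,0.23,-0.17
fine,PCNM387,0.20,0.16
fine,PCNM426,0.19,-0.16
fine,PCNM427,0.26,0.18
fine,PCNM436,0.35,-0.21
fine,PCNM466,0.29,0.19
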