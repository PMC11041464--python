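participant,triggered_cv,control_cv
1,0.276,0.196
2,0.215,0.436
3,0.467,0.777
4,0.343,0.699
5,0.143,0.202
6,0.390,0.410
7,0.534,0.419
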