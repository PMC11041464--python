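participant,initial_threshold,s1,s2,s3,s4,s5,s6,s7,s8,s9,s10,printed_mean
1,0.660,0.698,0.557,0.363,0.718,0.700,0.661,0.664,0.684,0.435,0.607,0.609
2,0.770,0.856,0.777,0.792,0.786,0.828,0.781,0.826,0.744,0.817,0.579,0.773
3,0.530,0.624,0.632,0.569,0.627,0.551,0.571,0.545,0.620,0.559,0.430,0.560
4,0.570,0.635,0.388,0.580,0.950,0.600,0.416,0.445,0.669,0.648,0.684,0.601
5,0.695,0.720,0.937,0.612,0.754,0.962,0.657,0.719,0.746,0.955,0.442,0.750
6,0.671,0.672,0.676,0.748,0.724,0.762,0.696,0.702,0.671,0.685,0.672,0.692
7,0.670,0.672,0.341,0.557,0.271,0.606,0.403,0.359,0.633,0.475,0.322,0.464
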