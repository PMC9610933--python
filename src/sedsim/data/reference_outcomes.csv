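regimen_id,T_rm,T_ro,range_lo,range_hi,deep_ratio
1,44.1,37.4,24.6,50.2,
2,31.1,35.3,27.6,43.0,
3,16.4,25.0,22.0,28.0,0.00
4,39.5,38.0,31.0,45.0,0.71
5,39.5,41.0,21.0,41.0,0.94
6,48.1,55.0,35.0,55.0,1.00
7,27.9,30.4,27.8,33.0,0.83
8,19.8,21.4,19.7,23.1,0.26
9,46.9,49.4,41.5,57.2,1.00
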