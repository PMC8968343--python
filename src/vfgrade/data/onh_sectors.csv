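cluster_id,angle_start_deg,angle_end_deg
1,324,360
2,288,324
3,252,288
4,216,252
5,180,216
6,144,180
7,108,144
8,72,108
9,36,72
10,0,36
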