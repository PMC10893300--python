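# sensor_id, t_seconds, then alternating angle_deg,range_m pairs
s0,0.000000,-30.000000,2.000000,0.000000,1.500000,30.000000,2.500000
s0,0.025000,-30.000000,2.010000,0.000000,1.490000,30.000000,2.510000
s1,0.000000,-15.000000,3.000000,15.000000,3.200000
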