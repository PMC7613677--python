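# Dimension-tag vocabulary for the dim_5 / dim_6 / dim_7 keys, one tag per line.
# DIM_USER_0..2 are additionally always accepted for user-defined purposes.
DIM_COIL
DIM_DYN
DIM_INDIRECT
DIM_PHASE_CYCLE
DIM_EDIT
DIM_MEAS
DIM_ISIS
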