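patient,age,gender,preop_cbct_to_surgery_days,surgery_to_postop_cbct_days,preop_cbct_to_postop_cbct_days,planned_maxillary_advancement_mm
P1,17,M,56,101,157,5
P2,19,F,12,42,54,4.5
P3,20,M,24,80,104,3.5
P4,27,M,26,43,69,4.5
P5,18,M,18,94,112,5.5
P6,35,F,26,59,85,4.5
P7,17,M,13,64,77,5.5
P8,32,F,580,49,629,4
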