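name,value,low,high,units,source
utility_stage_a,0.74,,,utility weight,meta-analysis by CRC stage
utility_stage_b,0.74,,,utility weight,meta-analysis by CRC stage
utility_stage_c,0.74,,,utility weight,meta-analysis by CRC stage
utility_stage_d,0.68,,,utility weight,meta-analysis by CRC stage
utility_norm_50_69,0.80,,,utility weight,Australian population norms
utility_norm_70_79,0.76,,,utility weight,Australian population norms
utility_norm_80p,0.70,,,utility weight,Australian population norms
discount_rate,0.05,,,proportion per year,Australian pharmaceutical evaluation guidelines
wtp_threshold,50000,,,AUD per QALY,Australian willingness-to-pay convention
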