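name,value,low,high,units,source
crc_incidence_50_54,0.0007,,,probability per person-year,Victorian Cancer Registry 2019 age-specific rates
crc_incidence_55_59,0.0008,,,probability per person-year,Victorian Cancer Registry 2019 age-specific rates
crc_incidence_60_64,0.0012,,,probability per person-year,Victorian Cancer Registry 2019 age-specific rates
crc_incidence_65_69,0.0016,,,probability per person-year,Victorian Cancer Registry 2019 age-specific rates
crc_incidence_70_74,0.0019,,,probability per person-year,Victorian Cancer Registry 2019 age-specific rates
crc_incidence_75_79,0.0026,,,probability per person-year,Victorian Cancer Registry 2019 age-specific rates
crc_incidence_80_84,0.0031,,,probability per person-year,Victorian Cancer Registry 2019 age-specific rates
crc_incidence_85p,0.0037,,,probability per person-year,Victorian Cancer Registry 2019 age-specific rates
progressive_adenoma_incidence_50_54,0.0038,,,probability per person-year,CRC incidence shifted 20 years (age-adjusted)
progressive_adenoma_incidence_55_59,0.0041,,,probability per person-year,CRC incidence shifted 20 years (age-adjusted)
progressive_adenoma_incidence_60_64,0.0062,,,probability per person-year,CRC incidence shifted 20 years (age-adjusted)
progressive_adenoma_incidence_65p,0.0068,,,probability per person-year,CRC incidence shifted 20 years (age-adjusted)
all_adenoma_incidence_printed_50_54,0.0012,,,probability per person-year,printed table row; inconsistent with derivation rule and unused
all_adenoma_incidence_printed_55_59,0.0015,,,probability per person-year,printed table row; inconsistent with derivation rule and unused
all_adenoma_incidence_printed_60_64,0.0019,,,probability per person-year,printed table row; inconsistent with derivation rule and unused
all_adenoma_incidence_printed_65p,0.0025,,,probability per person-year,printed table row; inconsistent with derivation rule and unused
low_risk_adenoma_incidence_printed_50_54,0.0160,,,probability per person-year,printed table row; alternative preset
low_risk_adenoma_incidence_printed_55_59,0.0173,,,probability per person-year,printed table row; alternative preset
low_risk_adenoma_incidence_printed_60_64,0.0257,,,probability per person-year,printed table row; alternative preset
low_risk_adenoma_incidence_printed_65p,0.0282,,,probability per person-year,printed table row; alternative preset
progressive_fraction,0.24,,,proportion,proportion of all adenomas that become progressive
transition_low_to_high,0.02,0.01,0.04,probability per year,Frazier et al
transition_high_to_crc,0.05,0.02,0.10,probability per year,Frazier et al
transition_a_to_b,0.05,0.02,0.10,probability per year,Frazier et al
transition_b_to_c,0.28,0.10,0.50,probability per year,Frazier et al
transition_c_to_d,0.28,0.10,0.50,probability per year,assumed equal to b_to_c (row absent from source table)
symptomatic_dx_a,0.22,0.20,0.24,probability per year,derived from not-screened stage distribution
symptomatic_dx_b,0.35,0.25,0.45,probability per year,derived from not-screened stage distribution
symptomatic_dx_c,0.59,0.49,0.69,probability per year,derived from not-screened stage distribution
symptomatic_dx_d,1.0,0.90,1.0,probability per year,derived from not-screened stage distribution
stage_screened_a,0.49,,,proportion,Victorian Cancer Registry 2009-2019
stage_screened_b,0.19,,,proportion,Victorian Cancer Registry 2009-2019
stage_screened_c,0.24,,,proportion,Victorian Cancer Registry 2009-2019
stage_screened_d,0.08,,,proportion,Victorian Cancer Registry 2009-2019
stage_not_screened_a,0.22,,,proportion,Victorian Cancer Registry 2009-2019
stage_not_screened_b,0.32,,,proportion,Victorian Cancer Registry 2009-2019
stage_not_screened_c,0.27,,,proportion,Victorian Cancer Registry 2009-2019
stage_not_screened_d,0.19,,,proportion,Victorian Cancer Registry 2009-2019
colonoscopy_prevalence_free,0.8740,,,proportion,AIHW 2021 diagnostic-assessment outcomes (printed values sum to 1.0227)
colonoscopy_prevalence_low,0.0609,,,proportion,AIHW 2021 diagnostic-assessment outcomes
colonoscopy_prevalence_high,0.0565,,,proportion,AIHW 2021 diagnostic-assessment outcomes
colonoscopy_prevalence_crc,0.0313,,,proportion,AIHW 2021 diagnostic-assessment outcomes
positivity_lote,0.064,,,probability per returned kit,AIHW 2021 screening positivity 2019
positivity_english,0.069,,,probability per returned kit,AIHW 2021 screening positivity 2019
followup_lote,0.543,,,probability per positive kit,AIHW 2021 colonoscopy assessment rate 2019
followup_english,0.631,,,probability per positive kit,AIHW 2021 colonoscopy assessment rate 2019
participation_arabic,0.307,,,probability per invitation,screening-register kit returns / eligible population
participation_mandarin,0.40,,,probability per invitation,screening-register kit returns / eligible population
max_age,100,,,years,model assumption
surveillance_interval,5,,,years,surveillance colonoscopy every five years
surveillance_max_age,75,,,years,surveillance ends at age 75
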