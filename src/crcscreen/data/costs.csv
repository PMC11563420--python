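name,value,low,high,units,source
fobt_kit,8.00,,,AUD 2019,assumption based on previous Australian study (printed range 10-12 incoherent; treated as fixed)
packaging_postage,2.40,,,AUD 2019,mailing and return postage
lab_analysis,17.85,,,AUD 2019,MBS item 66767
gp_consult,37.60,,,AUD 2019,MBS item 237
colonoscopy_no_polypectomy,2258,,,AUD 2019,AR-DRG G48B inflated to 2019
colonoscopy_polypectomy,4203,,,AUD 2019,AR-DRG G47B inflated to 2019
treatment_a,40999,37657,46025,AUD 2019,stage-specific mean treatment cost (range plus/minus 10 percent)
treatment_b,52594,48307,59041,AUD 2019,stage-specific mean treatment cost
treatment_c,95754,87948,107492,AUD 2019,stage-specific mean treatment cost
treatment_d,90272,82913,101338,AUD 2019,stage-specific mean treatment cost averaged over bevacizumab use
intervention_total_arabic,120863,,,AUD 2019,total recruitment program cost Arabic 2019
intervention_total_mandarin,120337,,,AUD 2019,total recruitment program cost Mandarin 2019
eligible_population_arabic,17522,,,persons,census interpolation to 2019
eligible_population_mandarin,38660,,,persons,census interpolation to 2019
reference_year,2019,,,calendar year,cost reference year
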