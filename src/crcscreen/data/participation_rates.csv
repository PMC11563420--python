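area,proxy_for,rate_2018,rate_2019,irr,irr_low,irr_high
Whitehorse,mandarin,0.478,0.532,1.20,1.05,1.37
Hume,arabic,0.401,0.444,1.17,1.03,1.33
Victoria,,0.442,0.490,1.18,1.05,1.33
South Australia,control,0.469,0.512,1.15,0.98,1.33
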