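scenario,fixed_area_increment_tg,restoration_increment_tg,gwp_tg_co2eq
rcp26,0.15,0.18,3.65
rcp45,0.58,0.73,14.62
rcp85,1.21,1.52,30.49
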