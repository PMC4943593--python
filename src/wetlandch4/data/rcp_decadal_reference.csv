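scenario,decade_start,decade_end,dT_c,dP_mm,dANPP_g_m2,dCH4_g_m2
rcp26,2011,2020,0.40,75.3,14.6,9.1
rcp26,2021,2030,0.81,35.7,35.9,9.3
rcp26,2031,2040,1.30,24.7,50.0,5.6
rcp26,2041,2050,0.37,21.5,59.2,2.4
rcp26,2051,2060,0.45,65.2,59.2,7.3
rcp26,2061,2070,0.40,-6.5,56.4,-8.0
rcp26,2071,2080,0.01,70.9,53.8,8.9
rcp26,2081,2090,0.05,0.8,46.1,-2.0
rcp26,2091,2100,-0.75,81.1,38.2,5.7
rcp45,2011,2020,0.79,21.2,8.8,-2.2
rcp45,2021,2030,0.69,78.5,27.3,10.2
rcp45,2031,2040,1.13,43.3,46.7,8.2
rcp45,2041,2050,2.34,5.0,66.7,12.5
rcp45,2051,2060,1.76,78.5,85.7,21.3
rcp45,2061,2070,2.07,96.7,101.2,38.0
rcp45,2071,2080,2.47,65.1,109.7,44.6
rcp45,2081,2090,2.54,74.5,112.5,40.8
rcp45,2091,2100,2.73,76.6,116.6,57.5
rcp85,2011,2020,0.35,81.6,14.7,2.2
rcp85,2021,2030,1.29,-57.0,26.5,-11.0
rcp85,2031,2040,2.14,54.9,44.1,11.5
rcp85,2041,2050,2.80,103.5,67.4,36.8
rcp85,2051,2060,3.75,37.3,95.0,31.8
rcp85,2061,2070,3.91,96.9,128.7,52.4
rcp85,2071,2080,5.38,35.5,165.1,48.9
rcp85,2081,2090,5.86,69.6,206.9,66.1
rcp85,2091,2100,5.42,133.0,250.4,112.2
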