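name,resistance_kohm,max_power_tw,heating_d1_gj,heating_d2_gj,heating_d3_gj
Jacaranda copaia,1275,1154,18.9,27.6,24.7
Alseis blackiana,2062,1867,30.6,44.7,40.0
Dipteryx panamensis,1284,1163,19.0,27.9,25.0
Acer rubrum,1716,1554,25.4,37.2,33.3
Acer saccharum,2615,2368,38.8,56.7,50.7
Quercus rubra,2359,2136,35.0,51.2,45.8
Betula alleghaniensis,2471,2238,36.6,53.6,48.0
Pinus virginiana,2706,2450,40.1,58.7,52.5
Pinus resinosa,3685,3336,54.6,80.0,71.5
Pinus strobus,2406,2178,35.7,52.2,46.7
Tsuga canadensis,2306,2088,34.2,50.0,44.8
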