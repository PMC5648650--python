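name,heating_0l_gj,heating_1l_gj,heating_3l_gj,power_0l_tw,power_1l_tw,power_3l_tw,diverted_1l_pct,diverted_3l_pct
Jacaranda copaia,18.9,9.27,3.63,1154,566,222,51,81
Alseis blackiana,30.6,10.7,3.23,1867,653,197,65,89
Dipteryx panamensis,19.0,9.3,3.62,1163,569,222,51,81
Acer rubrum,25.4,12.6,4.79,1554,771,293,50,81
Acer saccharum,38.8,14.0,4.34,2368,854,265,64,89
Quercus rubra,35.0,13.7,4.48,2136,836,273,61,87
Betula alleghaniensis,36.6,13.9,4.42,2238,850,270,62,88
Pinus virginiana,40.1,14.1,4.29,2450,862,262,65,89
Pinus resinosa,54.6,14.6,3.78,3336,892,231,73,93
Pinus strobus,35.7,13.8,4.46,2178,842,272,61,88
Tsuga canadensis,34.2,13.6,4.51,2088,830,275,60,87
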