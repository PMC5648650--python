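species,height_m,basal_diameter_cm,resistance_kohm,volume_m3,max_power_tw,heating_gj,heat_density_kj_cm3
Dipteryx panamensis,30,47.4,1525,1.80,1380,22.6,12.5
Dipteryx panamensis,25,37.0,1394,0.92,1262,20.7,22.5
Dipteryx panamensis,22,31.1,1326,0.58,1200,19.6,34.2
Dipteryx panamensis,20,27.3,1284,0.40,1163,19.0,47.0
Dipteryx panamensis,18,23.7,1244,0.28,1126,18.4,66.7
Dipteryx panamensis,15,18.5,1190,0.14,1077,17.6,124.3
Dipteryx panamensis,10,10.6,1114,0.03,1009,16.5,509.7
Alseis blackiana,30,38.3,2633,1.18,2384,39.0,33.0
Alseis blackiana,25,29.5,2477,0.59,2243,36.7,62.3
Alseis blackiana,22,24.6,2396,0.36,2169,35.5,97.8
Alseis blackiana,20,21.4,2352,0.25,2130,34.9,138.7
Alseis blackiana,18,18.5,2302,0.17,2085,34.1,200.4
Alseis blackiana,15,14.2,2251,0.09,2038,33.4,392.1
Alseis blackiana,10,8.0,2171,0.02,1966,32.2,1684.8
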