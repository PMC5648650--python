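name,region,growth_form,slope,intercept
Jacaranda copaia,tropical,tree,8.29,2.07
Alseis blackiana,tropical,tree,8.66,2.39
Dipteryx panamensis,tropical,tree,8.77,1.87
Acer rubrum,temperate,tree,8.46,2.29
Acer saccharum,temperate,tree,8.17,2.83
Quercus rubra,temperate,tree,8.42,2.63
Betula alleghaniensis,temperate,tree,8.23,2.75
Pinus virginiana,temperate,tree,9.09,2.51
Pinus resinosa,temperate,tree,7.91,3.28
Pinus strobus,temperate,tree,8.66,2.55
Tsuga canadensis,temperate,tree,8.89,2.41
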