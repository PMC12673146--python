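code,name,subcatchment_km2,upstream_km2,altitude_m,lat,lon
M1,Hakakondogoro,22.74,22.74,1839.5,-1.1521,29.9252
M2,Kakore East,61.45,61.45,1838.5,-1.1544,29.9293
M3,Mukirwa,7.38,7.38,1837.7,-1.1877,29.9257
M4,Ihanga FGC,18.45,110.02,1827.1,-1.1945,29.9300
M5,Ihanga,16.23,19.57,1832.9,-1.1980,29.9281
M6,Ihanga West,3.34,3.34,1849.9,-1.1995,29.9240
M7,Rwakaraba Bridge,32.44,162.03,1800.8,-1.2478,29.9819
M8,Lower Bugongi,9.10,9.10,1803.9,-1.2457,29.9860
M9,Brazin Forest,11.98,11.98,1803.5,-1.2609,29.9799
M10,Rugyendira,99.19,399.84,1791.3,-1.2724,29.9959
M11,Muvumba,226.22,300.65,1805.1,-1.4151,30.0105
M12,Katuna,74.43,74.43,1806.5,-1.4238,30.0119
M13,Butobere,26.15,26.15,1796.5,-1.2537,30.0169
M14,Kyanamira Bridge,25.22,634.32,1786.5,-1.2624,30.0282
M15,Kabanyonyi,32.30,32.30,1759.7,-1.3207,30.0781
M16,Maziba Dam,55.08,721.70,1757.7,-1.3152,30.0904
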