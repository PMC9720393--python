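site,mode,region,consecutive_years,rice_variety,tillage_per_year,irrigation_1e3m3_ha,organic_fertilizer_1e3kg_ha,green_manure_1e3kg_ha,crayfish_kg_ha,duckling_per_ha,hand_weeding_h_ha
TS,RG,north,3,Nanjing9108,4,5.6,6.0,27.6,0,0,41
QF,RG,middle,10,Nanjing9108,4,5.4,5.9,29.6,0,0,43
HS,RG,south,5,Nanjing46,4,5.6,6.1,26.4,0,0,42
WJ,RM,north,3,Nanjing9108,3,5.6,13.1,0,0,0,41
HJ,RM,middle,8,Nanjing9108,3,5.5,12.8,0,0,0,43.5
TL,RM,south,5,Nanjing46,3,5.6,12.9,0,0,0,43
YS,RC,north,6,Nanjing9108,3,7.8,5.4,0,442.5,0,19.5
QN,RC,middle,3,Nanjing9108,3,8.0,5.5,0,427.5,0,21.5
XB,RC,south,8,Nanjing9108,3,7.7,5.3,0,480,0,21
BP,RD,north,4,Nanjing9108,3,6.5,6.1,0,0,270,24
DY,RD,middle,6,Nanjing46,3,6.3,6.1,0,0,240,23
YX,RD,south,10,Nanjing46,3,6.1,5.9,0,0,255,21
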