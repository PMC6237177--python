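district,vi,tertile,hospitals_per_100k,public_hospitals_per_100k,private_hospitals_per_100k,claims_per_100k,public_claims_per_100k,private_claims_per_100k
Sukma,4.9,HVD,6.8,3.4,3.4,399,334,65
Bijapur,4.7,HVD,4.5,4.5,0.0,5628,5628,0
Narayanpur,4.5,HVD,7.3,4.9,2.4,6762,5052,1709
Kondagaon,4.3,HVD,4.8,2.9,1.9,3441,1247,2194
Balrampur,4.2,HVD,5.5,5.2,0.3,1718,1341,377
Dantewada,4.2,HVD,3.9,3.9,0.0,4053,4053,0
Jashpur,3.9,HVD,3.0,2.6,0.4,2672,1289,1383
Surajpur,3.8,HVD,1.3,1.1,0.1,937,893,44
Bastar,3.7,HVD,3.5,2.6,1.0,3492,1968,1524
Kanker,3.6,MVD,5.8,4.0,1.9,6841,3462,3379
Sarguja,3.4,MVD,5.6,3.0,2.6,7185,2427,4758
Gariyabandh,3.3,MVD,2.4,1.6,0.8,878,649,229
Kawardha,3.3,MVD,3.3,1.1,2.2,1890,161,1730
Koria,3.2,MVD,3.0,2.1,0.9,3001,2061,940
Mungeli,3.2,MVD,2.0,0.8,1.2,1215,25,1190
Korba,3.1,MVD,5.4,1.2,4.2,3928,872,3056
Mahasamund,3.0,MVD,2.7,0.8,1.9,2693,634,2059
Bemetara,2.9,MVD,1.5,1.2,0.3,933,575,358
Balodabazar,2.9,LVD,2.5,1.4,1.2,1583,1202,381
Raigarh,2.8,LVD,6.0,3.2,2.7,3148,686,2461
Rajnandgaon,2.7,LVD,8.5,5.2,3.3,5120,1327,3793
Balod,2.6,LVD,3.4,1.4,2.0,3882,841,3041
Janjgir,2.4,LVD,2.3,1.0,1.3,2590,937,1653
Dhamtari,2.1,LVD,9.0,4.7,4.3,12849,2511,10338
Bilaspur,1.7,LVD,11.6,1.5,10.1,15000,1092,13908
Durg,0.6,LVD,9.4,2.2,7.3,7428,1449,5978
Raipur,0.2,LVD,18.7,1.0,17.7,20042,3136,16906
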