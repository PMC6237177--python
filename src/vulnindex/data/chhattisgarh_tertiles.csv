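indicator,HVD,MVD,LVD,state,ratio_mvd_hvd,ratio_lvd_hvd
hospitals_total_n,83,142,510,735,,
hospitals_per_100k,3.4,3.7,8.2,5.9,1.1,2.4
public_hospitals_per_100k,2.8,1.8,2.2,2.2,0.6,0.8
private_hospitals_per_100k,0.6,1.9,6,3.7,3.2,10
claims_total_n,59432,133237,516104,708773,,
claims_per_100k,2399.7,3480.3,8341.8,5673.9,1.5,3.5
public_claims_per_100k,1606.0,1291.9,1461.0,1437.9,0.8,0.9
private_claims_per_100k,793.7,2188.4,6880.9,4235.9,2.8,8.7
claims_amount_total_inr_million,307,780,2778,3864.9,,
claims_amount_per_100k,124.1,203.6,449.0,309.4,1.6,3.6
public_claims_amount_per_100k,70.3,49.1,48.3,52.9,0.7,0.7
private_claims_amount_per_100k,53.9,154.6,400.6,256.5,2.9,7.4
enrolment_coverage_pct,52.5,51.7,46.1,,,
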