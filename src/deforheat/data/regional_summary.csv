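scope,areawgt_dt_nondefor,popwgt_dt_nondefor,areawgt_dt_defor,popwgt_dt_defor,areawgt_dt_induced,popwgt_dt_induced,pop_forest_loss,pop_exposed,deaths_central,deaths_low,deaths_high
tropics,0.20,0.19,0.70,0.70,0.45,0.27,452000000,345000000,28330,23610,33560
tropical_central_south_america,0.30,-0.12,0.73,0.40,0.53,0.22,89800000,66900000,2520,2160,2950
tropical_africa,0.08,0.12,0.75,0.97,0.39,0.32,185000000,148000000,9890,8250,11850
southeast_asia,0.31,0.36,0.61,0.56,0.37,0.26,165000000,122000000,15680,13000,18470
indonesia,,,,,,,62900000,48900000,6730,5540,7930
malaysia,,,,,,,17500000,15300000,2100,1680,2550
vietnam,,,,,,,10900000,6950000,2020,1730,2310
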