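key,hvi_pct_per_C,parent,basis
south_america,2.34,,non_accidental
southeast_asia,5.29,,non_accidental
africa,,south_america,non_accidental
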