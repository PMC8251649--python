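# mitodose optical constants table, version 1
# material, lambda0_nm, n_real, mu_a_per_m
material,lambda0_nm,n_real,mu_a_per_m
air,808,1.0,0.0
air,980,1.0,0.0
air,1064,1.0,0.0
saline,808,1.331,1.95
saline,980,1.328,50.2
saline,1064,1.328,16.2
glass,808,1.511,0.170
glass,980,1.508,0.122
glass,1064,1.507,0.099
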