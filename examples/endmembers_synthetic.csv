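name,delta13C_permil,sigma13,Delta14C_permil,sigma14
phytoplankton,-20.0,1.0,50.0,50.0
acetate_ferm,-38.0,1.0,-250.0,50.0
pre_aged,-27.0,1.0,-900.0,50.0
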