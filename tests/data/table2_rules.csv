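rule_id,support,confidence,lift,n
sga_mixture,0.02348987246811703,0.10895071608512297,1.2233507239249042,333250
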