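gere
ykud
sigk
sigk factor
renin
aldosterone
p53
mdm2
insulin
cyclin d1
cdk4
bcl-2
bax
akt1
raf1
egfr
grb2
sos1
stat3
jak2
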