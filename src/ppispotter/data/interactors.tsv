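bind	VB
activate	VB
inhibit	VB
interact	VB
phosphorylate	VB
regulate	VB
associate	VB
suppress	VB
stimulate	VB
block	VB
induce	VB
mediate	VB
modulate	VB
repress	VB
cleave	VB
recruit	VB
stabilize	VB
degrade	VB
acetylate	VB
ubiquitinate	VB
target	VB
response	NN
interaction	NN
association	NN
complex	NN
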