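not only
no increase
no change
no further
not necessarily
without difficulty
gram negative
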