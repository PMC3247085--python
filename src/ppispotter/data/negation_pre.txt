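no
not
without
neither
lack of
absence of
failed to
unable to
no evidence of
no evidence that
cannot
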