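was ruled out
were ruled out
was not observed
were not observed
was not detected
were not detected
is unlikely
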