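instance,match_percentage
all,19.2
P1,57.6
P2,42.3
P3,46.1
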