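d0	4.10306365822
s02	0.0526504560357
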