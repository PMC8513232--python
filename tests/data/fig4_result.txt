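B C D B A A
4 3 3 1 3
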