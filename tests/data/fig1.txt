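I B B A C A A F
5 1 4 3 1 3 2
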