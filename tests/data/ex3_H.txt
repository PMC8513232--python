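I B C A B B C F
1 3 0 2 4 3 2
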