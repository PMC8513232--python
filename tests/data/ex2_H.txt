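C D E A A E B D E
4 3 1 1 2 1 1 3
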