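A E B C A E D E D
2 1 2 2 1 3 2 3
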