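subject,scan1,scan2
1,8.99,8.92
2,9.35,9.20
3,8.93,9.18
4,10.44,10.28
5,10.08,10.32
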