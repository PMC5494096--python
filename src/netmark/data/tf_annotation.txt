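FOS
FOSB
KLF4
KLF9
ZFP36
SPDEF
HOXA5
ETS2
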