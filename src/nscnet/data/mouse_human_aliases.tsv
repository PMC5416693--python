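mouse	human
Mll2	MLL2
Kmt2d	MLL2
Kmt2a	MLL
2610301B20Rik	AHDC1
Kiaa1279	KIF1BP
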