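label,charge,mz
me0,2,809.45720
me0,3,539.97389
me1-free,2,788.45191
me1-free,3,525.97037
me1-prop,2,816.46502
me1-prop,3,544.64577
me2,2,795.45974
me2,3,530.64225
me3,2,802.46756
me3,3,535.31413
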