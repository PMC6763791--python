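# Tryptic peptides by which p62/SQSTM1 was identified in the CB2 pulldown
AGEARPGPTAESASGPSEDPSVNFLK
CSVCPDYDLCSVCEGK
DHRPPCAQEAPR
LTPVSPESSSTEEK
NMVHPNVICDGCNGPVVGTR
NYDIGAALDTIQYSK
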