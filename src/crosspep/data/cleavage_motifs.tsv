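context6	proteases	source	notes
PGKQGA	MMP2,MMP3,MMP8,MMP12,MMP13	custom
PQGFQG	MMP2,MMP3,MMP9,MMP12	custom
PAGERG	MMP2,MMP9,MMP13	custom
PSGFQG	MMP3,MMP8,MMP9,MMP12,MMP13	custom
PRGLPG	MMP8,MMP9,MMP12,MMP13	custom
PAGQPG	MMP8,MMP9,MMP12,ADAMTS4	custom	MMP9 MEROPS-only
PPGKNG	MMP9,MMP13	custom
QPGSPG	MMP9,MMP13	custom
PRGERG	MMP9	custom
PAGQQG	MMP8,MMP9,MMP12,MMP13	custom	MMP8/MMP9 MEROPS-only
PGPSGK	ADAMTS5	custom
PGPAGP	ADAMTS5	custom
GPRGPP	CTSK,F2	custom	CTSK CutDB-only
PPQEKA	CTSK	custom
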