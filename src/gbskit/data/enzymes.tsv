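# Default restriction enzyme annotation.
# Columns: name<TAB>recognition (with '^' marking the top-strand cut)[<TAB>remnant]
# Extend or override with your own file via --enzymes / parse_enzyme_file().
ApeKI	G^CWGC	CWGC
ApoI	R^AATTY	AATTY
AseI	AT^TAAT	TAAT
BamHI	G^GATCC	GATCC
ClaI	AT^CGAT	CGAT
DpnII	^GATC	GATC
EcoRI	G^AATTC	AATTC
EcoRV	GAT^ATC	ATC
EcoT22I	ATGCA^T	T
HindIII	A^AGCTT	AGCTT
KpnI	GGTAC^C	C
MluCI	^AATT	AATT
MseI	T^TAA	TAA
MspI	C^CGG	CGG
NdeI	CA^TATG	TATG
NlaIII	CATG^	CATG
NotI	GC^GGCCGC	GGCCGC
NsiI	ATGCA^T	T
PstI	CTGCA^G	G
SacI	GAGCT^C	C
Sau3AI	^GATC	GATC
SbfI	CCTGCA^GG	GG
SgrAI	CR^CCGGYG	CCGGYG
SpeI	A^CTAGT	CTAGT
SphI	GCATG^C	C
TaqI	T^CGA	CGA
XbaI	T^CTAGA	CTAGA
XhoI	C^TCGAG	TCGAG
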