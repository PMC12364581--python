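Source	Target	Type
TBX21	GATA3	2
TBX21	RORC	2
TBX21	FOXP3	2
TBX21	BCL6	2
GATA3	TBX21	2
GATA3	RORC	2
GATA3	FOXP3	2
RORC	TBX21	2
RORC	GATA3	2
RORC	FOXP3	2
FOXP3	TBX21	2
FOXP3	GATA3	2
FOXP3	RORC	2
BCL6	TBX21	2
BCL6	GATA3	2
BCL6	RORC	2
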