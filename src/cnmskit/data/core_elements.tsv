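# Reference regulatory-element signal library (name, signal consensus, source)
GAGA8HVBKN3	(GA)8	PLACE
CTRMCAMV35S	TCTCTCTCT	PLACE
RAV1AAT	CAACA	PLACE
S1FBOXSORPS1L21	ATGGTA	PLACE
CANBNNAPA	CNAACAC	PLACE
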