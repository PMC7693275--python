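# Transliteration table for genus/epithet tokens.
# One mapping per line: <character><TAB><replacement>.
# Scientific name tokens may only contain A-Z, a-z and '-' after
# normalization; umlauted vowels expand to digraphs, other accented
# letters drop their diacritic.
ä	ae
ö	oe
ü	ue
Ä	Ae
Ö	Oe
Ü	Ue
ë	e
ï	i
ÿ	y
á	a
à	a
â	a
ã	a
å	a
æ	ae
Á	A
À	A
Â	A
Ã	A
Å	A
Æ	Ae
é	e
è	e
ê	e
ē	e
É	E
È	E
Ê	E
í	i
ì	i
î	i
Í	I
Ì	I
Î	I
ó	o
ò	o
ô	o
õ	o
ø	oe
œ	oe
Ó	O
Ò	O
Ô	O
Õ	O
Ø	Oe
Œ	Oe
ú	u
ù	u
û	u
Ú	U
Ù	U
Û	U
ñ	n
Ñ	N
ç	c
Ç	C
ß	ss
ý	y
Ý	Y
š	s
Š	S
ž	z
Ž	Z
č	c
Č	C
ł	l
Ł	L
đ	d
Đ	D
ř	r
Ř	R
ć	c
Ć	C
ń	n
ś	s
ź	z
ż	z
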