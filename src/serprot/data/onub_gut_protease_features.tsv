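id	family	activation	his	asp	ser	cys_count	s1	designation	partial
OnTry1	trypsin	Arg	His	Asp	Ser	6	Asp	putative	0
OnTry2	trypsin	Arg	His	Asp	Ser	6	Asp	putative	0
OnTry3	trypsin	Arg	His	Asp	Ser	6	Asp	putative	0
OnTry4	trypsin	Arg	His	Asp	Ser	6	Asp	putative	0
OnTry5	trypsin	Arg	His	Asp	Ser	6	Asp	putative	0
OnTry6	trypsin	Arg	His	Asp	Ser	6	Asp	putative	0
OnTry7	trypsin	Arg	His	Asp	Ser	6	Asp	putative	0
OnTry10	trypsin	Arg	His	Asp	Ser	6	Asp	putative	0
OnTry11	trypsin	Arg	His	Asp	Ser	6	Asp	putative	0
OnTry14	trypsin	Arg	His	Asp	Ser	6	Asp	putative	1
OnTry22	trypsin	Arg	His	Asp	Ser	6	Asp	putative	0
OnTry23	trypsin	Arg	His	Asp	Ser	6	Asp	putative	0
OnTry8	trypsin	Arg	Tyr	Asp	Glu	6	Asp	homolog	0
OnTry9	trypsin	Arg	Ser	Asp	Asn	6	Gly	homolog	0
OnTry12	trypsin	Arg	Ser	Asp	Val	6	Gly	homolog	0
OnTry13	trypsin	Arg	His	Asp	Ser	6	Ser	homolog	0
OnTry21	trypsin	Arg	His	Asp	Gly	6	Asp	homolog	0
OnCTP1	chymotrypsin	Arg	His	Asp	Ser	6	Gly	putative	0
OnCTP2	chymotrypsin	Arg	His	Asp	Ser	6	Ser	putative	0
OnCTP3	chymotrypsin	Arg	His	Asp	Ser	6	Gly	putative	0
OnCTP4	chymotrypsin	Arg	His	Asp	Ser	6	Gly	putative	0
OnCTP5	chymotrypsin	Arg	His	Asp	Ser	6	Gly	putative	0
OnCTP7	chymotrypsin	Arg	His	Asp	Ser	6	Gly	putative	0
OnCTP8	chymotrypsin	Arg	His	Asp	Ser	6	Gly	putative	0
OnCTP9	chymotrypsin	Arg	His	Asp	Ser	6	Ser	putative	0
OnCTP11	chymotrypsin	Arg	His	Asp	Ser	6	Ser	putative	0
OnCTP12	chymotrypsin	Arg	His	Asp	Ser	6	Ser	putative	0
OnCTP14	chymotrypsin	Arg	His	Asp	Ser	6	Gly	putative	0
OnCTP17	chymotrypsin	Arg	His	Asp	Ser	6	Gly	putative	1
OnCTP6	chymotrypsin	Arg	His	Asp	Thr	6	Gly	homolog	0
OnCTP10	chymotrypsin	Arg	His	Asp	Ser	6	Asn	homolog	0
OnCTP13	chymotrypsin	Pro	His	Asp	Ser	6	Gly	homolog	0
OnCTP15	chymotrypsin	His	His	Asp	Ser	6	Gly	homolog	0
OnCTP16	chymotrypsin	Arg	His	Asp	Ser	5	Gly	homolog	0
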