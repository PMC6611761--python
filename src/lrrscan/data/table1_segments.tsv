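hcs	discovery	start	end	window11	window12
HCS1	visual_inspection	305	315	LKVYEILPTFD
HCS2	scanprosite	329	340	LYNLFLEENIS	LYNLFLEENISE
HCS3	visual_inspection	344	355	YKCLKVLENIK	YKCLKVLENIKS
HCS4	visual_inspection	360	371	IDPMLLLTNLG	IDPMLLLTNLGM
HCS5	visual_inspection	376	387	IIDGKIPTSLQ	IIDGKIPTSLQT
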