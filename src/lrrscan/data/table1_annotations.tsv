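label	start	end	source
Endocytic recognition sequence (Y308-L311)	308	311	literature: YxxL endocytic motif
Phosphorylation site (Y308)	308	308	literature: phosphorylation site
Endocytic recognition sequence (Y330-F333)	330	333	literature: YxxL endocytic motif
Endocytic recognition sequence (Y344-L347)	344	347	literature: YxxL endocytic motif
Channel gating, S-nitrosylation site (C346)	346	346	literature: channel gating / S-nitrosylation
Putative membrane-interacting domain (I360-G370)	360	370	literature: secondary-structure study
Caspase-cleavage site (D375-D378)	375	378	literature: caspase cleavage
Beta-strand (K373-D380)	373	380	literature: secondary-structure study
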