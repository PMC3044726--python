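# Pharmacophoric feature perception rules, one per line:
# <kind><TAB><SMARTS>
# kind in {donor, acceptor}; the feature point is placed on the first
# matched atom. Hydrophobic features (aromatic-ring centroids and
# aliphatic carbon clusters) are perceived structurally, not by SMARTS.
# This rule list is a documented stand-in for proprietary feature
# definitions and is user-replaceable.
donor	[#7,#8;!H0]
acceptor	[OX1]
acceptor	[OX2;H0;!$(O=*)]
acceptor	[OX2H1]
acceptor	[nX2]
acceptor	[NX2;H0;!$(N=O)]
acceptor	[NX3;H0;!$(N[CX3]=[OX1]);!$(N(a)(a));!$([N+])]
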