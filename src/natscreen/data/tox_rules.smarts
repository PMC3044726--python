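# Representative toxicophore / reactive-group substructure rules, one per line:
# <rule_id><TAB><SMARTS>
# Covers the usual classes flagged by ADME/Tox triage tools: "warhead"
# electrophiles, chelators, frequent hitters and assay-promiscuous groups.
# The list is user-replaceable; pass any file in this format to admet_pass.
acyl_halide	[CX3](=O)[F,Cl,Br,I]
sulfonyl_halide	[SX4](=O)(=O)[F,Cl,Br,I]
anhydride	[CX3](=O)O[CX3](=O)
michael_acceptor_enone	[CX3]=[CX3][CX3]=[OX1]
michael_acceptor_acrylate	[CX3]=[CX3][CX3](=O)[OX2]
michael_acceptor_acrylonitrile	[CX3]=[CX3]C#N
vinyl_sulfone	[CX3]=[CX3][SX4](=O)=O
quinone	O=C1C=CC(=O)C=C1
nitroso	[NX2]=[OX1]
n_nitroso	[NX3][NX2]=[OX1]
nitro_aromatic	[c][N+](=O)[O-]
azo	[NX2]=[NX2]
azide	[NX2]=[N+]=[N-]
diazo	[CX3]=[N+]=[N-]
peroxide	[OX2][OX2]
aldehyde	[CX3H1]=[OX1]
thiol	[SX2H1]
isocyanate	[NX2]=C=[OX1]
isothiocyanate	[NX2]=C=[SX1]
epoxide	C1OC1
aziridine	C1NC1
beta_lactam	O=C1CCN1
alkyl_halide_activated	[CH2X4][Br,I]
hydrazine	[NX3][NX3]
hydroxylamine	[NX3][OX2H1]
imine_of_aldehyde	[CX3H1]=[NX2]
thiourea	[NX3]C(=[SX1])[NX3]
phosphonate_ester	P(=O)(O[CH3,CH2])O
crown_chelator_catechol	[OX2H1]c1ccccc1[OX2H1]
polyene	C=CC=CC=CC=C
acridine	c1ccc2nc3ccccc3cc2c1
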