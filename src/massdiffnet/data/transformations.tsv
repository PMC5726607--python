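name	formula	delta_mass	type_class
CH2	CH2	14.015650063799999	alkyl
C2H2	C2H2	26.0156500638	alkyl
H2O	H2O	18.0105646859	hydration
CO	CO	27.994914622099998	carbonyl
CO2	CO2	43.989829244199996	carboxyl
NH3	NH3	17.0265491009	amine
O	O	15.9949146221	oxidation
HPO3	HPO3	79.96633040820001	phosphorylation
SO3	SO3	79.9568145563	sulphation
methionine	C5H9NOS	131.0404846044	amino-acid
diphosphate	H2P2O6	159.93266081640002	phosphorylation
glucose-N-phosphate	C6H11O8P	242.0191538377	glycosylation
glyoxalate	C2H2O3	74.0003939301	carboxyl
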