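name	polarity	n	z	offset_mass
[M+H]+	+	1	1	1.0072764519
[M+Na]+	+	1	1	22.9892207
[M+K]+	+	1	1	38.9631579064
[M+NH4]+	+	1	1	18.0338255528
[M+ACN+H]+	+	1	1	42.033825552799996
[2M+H]+	+	2	1	1.0072764519
[2M+Na]+	+	2	1	22.9892207
[3M+H]+	+	3	1	1.0072764519
[M+2H]2+	+	1	2	2.0145529038
[M-H]-	-	1	1	-1.0072764519
[M+Cl]-	-	1	1	34.96940129
[M+HCOO]-	-	1	1	44.9982028561
[2M-H]-	-	2	1	-1.0072764519
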