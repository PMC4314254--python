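analyte,class,parent,rfd_group,rfd_mg_per_kg_day,rpf,lod_ng_per_g
benzo[a]anthracene,cpah7,,,,0.1,0.4087817653246333
chrysene,cpah7,,,,0.001,0.4087817653246333
benzo[b]fluoranthene,cpah7,,,,0.1,0.4087817653246333
benzo[k]fluoranthene,cpah7,,,,0.01,0.4087817653246333
benzo[a]pyrene,cpah7,,,,1.0,0.4087817653246333
"indeno[1,2,3-c,d]pyrene",cpah7,,,,0.1,0.4087817653246333
"dibenzo[a,h]anthracene",cpah7,,,,1.0,0.4087817653246333
naphthalene,unsubstituted,,naphthalene,0.02,,2
fluorene,unsubstituted,,fluorene,0.04,,2
anthracene,unsubstituted,,anthracene/phenanthrene,0.3,,3
phenanthrene,unsubstituted,,anthracene/phenanthrene,0.3,,2
pyrene,unsubstituted,,pyrene,0.03,,2
fluoranthene,unsubstituted,,fluoranthene,0.04,,3
biphenyl,unsubstituted,,,,,2
dibenzofuran,unsubstituted,,,,,2
acenaphthene,unsubstituted,,,,,3
acenaphthylene,unsubstituted,,,,,3
dibenzothiophene,unsubstituted,,,,,3
perylene,unsubstituted,,,,,3
benzo[e]pyrene,unsubstituted,,,,,4
"benzo[g,h,i]perylene",unsubstituted,,,,,4
carbazole,unsubstituted,,,,,4
retene,unsubstituted,,,,,4
2-methylnaphthalene,alkylated,naphthalene,,,,2
1-methylnaphthalene,alkylated,naphthalene,,,,2
C2-naphthalenes,alkylated,naphthalene,,,,2
C3-naphthalenes,alkylated,naphthalene,,,,3
1-methylphenanthrene,alkylated,phenanthrene,,,,2
C2-phenanthrenes,alkylated,phenanthrene,,,,3
C1-fluorenes,alkylated,fluorene,,,,2
C2-fluorenes,alkylated,fluorene,,,,3
C1-pyrenes,alkylated,pyrene,,,,2
C1-fluoranthenes,alkylated,fluoranthene,,,,2
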