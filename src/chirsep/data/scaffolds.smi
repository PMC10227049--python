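C[C@H](O)C(=O)O lactic_acid
C[C@H](N)C(=O)O alanine
CC[C@H](C)O butan-2-ol
C[C@H](O)c1ccccc1 1-phenylethanol
C[C@H](N)c1ccccc1 1-phenylethylamine
C[C@H](Cl)C(=O)O 2-chloropropanoic_acid
C[C@H](Br)C(=O)O 2-bromopropanoic_acid
C[C@H](O)C(=O)OC methyl_lactate
CC[C@H](N)C(=O)O 2-aminobutanoic_acid
C[C@H](O)CC(=O)O 3-hydroxybutanoic_acid
C[C@H](N)CO alaninol
C[C@H](O)CO propane-1,2-diol
C[C@H](C#N)c1ccccc1 2-phenylpropanenitrile
C[C@H](O)c1ccc(C)cc1 1-(4-tolyl)ethanol
C[C@H](O)c1ccc(Cl)cc1 1-(4-chlorophenyl)ethanol
C[C@H](O)c1ccc(F)cc1 1-(4-fluorophenyl)ethanol
C[C@H](O)c1ccc(OC)cc1 1-(4-methoxyphenyl)ethanol
C[C@H](N)c1ccc(C)cc1 1-(4-tolyl)ethylamine
C[C@H](O)c1ccccn1 1-(pyridin-2-yl)ethanol
CC(C)[C@H](N)C(=O)O valine
CC(C)C[C@H](N)C(=O)O leucine
C[C@H](O)C(C)(C)C 3,3-dimethylbutan-2-ol
CC[C@H](O)c1ccccc1 1-phenylpropan-1-ol
C[C@H](OC(C)=O)c1ccccc1 1-phenylethyl_acetate
C[C@H](F)C(=O)O 2-fluoropropanoic_acid
O[C@H](C(=O)O)c1ccccc1 mandelic_acid
N[C@H](C(=O)O)c1ccccc1 phenylglycine
C[C@H](Cc1ccccc1)N amphetamine
N[C@H](C(=O)O)Cc1ccccc1 phenylalanine
C[C@H](O)Cc1ccccc1 1-phenylpropan-2-ol
C[C@H](N)CC(C)C 4-methylpentan-2-amine
C[C@H](O)CCC pentan-2-ol
C[C@H](N)CCC pentan-2-amine
C[C@H](O)CCO butane-1,3-diol
C[C@H](C(=O)O)Cc1ccccc1 2-methyl-3-phenylpropanoic_acid
C[C@H](C(=O)OC)c1ccccc1 methyl_2-phenylpropanoate
C[C@H](C(=O)O)c1ccccc1 2-phenylpropanoic_acid
C[C@H](C(=O)O)c1ccc(C)cc1 2-(4-tolyl)propanoic_acid
C[C@H](C(=O)O)c1ccc(Cl)cc1 2-(4-chlorophenyl)propanoic_acid
C[C@H](C(=O)O)c1ccc(OC)cc1 2-(4-methoxyphenyl)propanoic_acid
C[C@H](C(N)=O)c1ccccc1 2-phenylpropanamide
C[C@H](O)C(=O)Nc1ccccc1 lactanilide
CO[C@H](C)c1ccccc1 1-methoxy-1-phenylethane
C[C@H](O)c1cccc(C)c1 1-(3-tolyl)ethanol
C[C@H](O)c1ccccc1C 1-(2-tolyl)ethanol
CC[C@H](C)c1ccccc1 2-phenylbutane
C[C@H](N)C(=O)OC methyl_alaninate
C[C@H](O)C#N lactonitrile
C[C@H](S)C(=O)O thiolactic_acid
C[C@H](O)C(=O)N(C)C N,N-dimethyllactamide
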