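1,4-Cyclohexane dicarboxylic acid
1-Adamantanecarboxylic acid
2-Hydroxybiphenyl
4-Phenylbutyric acid
5,6,7,8-Tetrahydro-2-naphthoic acid
Benzene
Cyclohexane
Cyclohexanecarboxylic acid
Cyclohexanone
Cyclopentanecarboxylic acid
Decane
Dodecane
Eicosane
Ethylbenzene
FuelOil
Heptadecane
Heptane
Hexadecane
Hexatriacontane
Naphthalene
Nonane
Octacosane
Tetracosane
Tetradecane
Toluene
Tridecane
Anthracene
Cyclohexane butyric acid
Cyclohexaneacetic acid
Decanoic acid
Dibenzothiophene
Gentisic acid
Hexane
Hexanoic acid
m-Xylene
Methyl-cyclohexanecarboxylic acid
o-Xylene
p-Xylene
Phenanthrene
Salicylic acid
Trans-1,2-cyclohexane dicarboxylic acid
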