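# Published substrate -> enzyme (EC) associations for the xenobiotic PM panel
# tested on R. opacus R7 and Rhodococcus sp. BCP1. Substrates without a row
# are reported as "unknown" by ec_association().
2-Hydroxybiphenyl	1.14.13.44; 3.13.1.3
Benzene	1.14.12.3; 1.14.13.-
Cyclohexane	1.14.15.-
Cyclohexanecarboxylic acid	6.2.1.-
Cyclohexanone	1.1.1.90; 1.1.1.245; 1.3.99.14; 1.4.3.12; 1.14.13.22; 4.1.3.35
Ethylbenzene	1.14.12.12; 1.14.12.-; 1.17.99.2; 1.17.-.-
Heptadecane	4.1.99.5
Naphthalene	1.14.12.12; 1.14.13.-; 1.14.14.1
Toluene	1.14.12.11; 1.14.13.-; 1.14.15.-; 4.1.99.11
Anthracene	1.14.12.12; 1.14.-.-
Decanoic acid	3.1.2.21
Gentisic acid	1.2.1.29; 1.2.3.1; 1.13.11.4; 1.14.13.24; 1.14.13.172; 4.1.1.62
Hexanoic acid	3.5.1.39
m-Xylene	1.14.13.-; 1.14.15.-
Methyl-cyclohexanecarboxylic acid	6.2.1.-
o-Xylene	1.14.13.-; 1.14.15.-
p-Xylene	1.14.13.-; 1.14.15.-
Phenanthrene	1.13.11.-; 1.14.13.-
Salicylic acid	1.2.1.65; 1.2.1.-; 1.14.13.1; 1.14.13.172; 1.14.13.-; 2.1.1.274; 3.1.1.55; 3.7.1.8; 4.1.1.91; 4.1.1.-; 4.2.99.21
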