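# Synthetic representative 33-analyte quantitative PAH panel (abbreviation, name).
# The six abbreviations used in diagnostic ratios (FLA, PYR, RET, CHR, PHE, ANT)
# are standard; the remaining rows are a typical quantitative panel lineup.
abbreviation	name
NAP	naphthalene
1MN	1-methylnaphthalene
2MN	2-methylnaphthalene
26DMN	2,6-dimethylnaphthalene
235TMN	2,3,5-trimethylnaphthalene
BIP	biphenyl
ACY	acenaphthylene
ACE	acenaphthene
DBF	dibenzofuran
FLO	fluorene
DBT	dibenzothiophene
PHE	phenanthrene
ANT	anthracene
1MP	1-methylphenanthrene
CAR	carbazole
FLA	fluoranthene
PYR	pyrene
RET	retene
BAA	benz[a]anthracene
CHR	chrysene
6MC	6-methylchrysene
BBF	benzo[b]fluoranthene
BJF	benzo[j]fluoranthene
BKF	benzo[k]fluoranthene
BEP	benzo[e]pyrene
BAP	benzo[a]pyrene
PER	perylene
IPY	indeno[1,2,3-cd]pyrene
DBA	dibenz[a,h]anthracene
BPE	benzo[g,h,i]perylene
CPP	cyclopenta[c,d]pyrene
DALP	dibenzo[a,l]pyrene
ANTN	anthanthrene
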