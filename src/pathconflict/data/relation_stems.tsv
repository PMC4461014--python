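stem	meta_relation
phosphorylate	increase
glycosylate	increase
acetylate	increase
accelerate	increase
accumul	increase
activat	increase
add	increase
agoni	increase
amplif	increase
augment	increase
elevat	increase
encod	increase
enhanc	increase
enrich	increase
express	increase
generat	increase
hyperexpr	increase
improv	increase
increas	increase
increment	increase
induc	increase
mediat	increase
overexpress	increase
overproduc	increase
produc	increase
releas	increase
result	increase
secret	increase
stimulat	increase
synthesis	increase
transactivat	increase
transcri	increase
translat	increase
trigger	increase
up-regulat	increase
yield	increase
attenuat	decrease
block	decrease
dephosphorylat	decrease
deacetylat	decrease
abolish	decrease
abrogat	decrease
antagoni	decrease
counteract	decrease
declin	decrease
decreas	decrease
degrad	decrease
deplet	decrease
depress	decrease
destruct	decrease
diminish	decrease
down-regulat	decrease
inactivat	decrease
inhibit	decrease
interfer	decrease
interrupt	decrease
obstruct	decrease
oppos	decrease
prevent	decrease
prohibit	decrease
reduc	decrease
remov	decrease
repress	decrease
suppress	decrease
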