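subtype	meta_relation
activation	increase
phosphorylation	increase
glycosylation	increase
methylation	increase
expression	increase
inhibition	decrease
dephosphorylation	decrease
repression	decrease
indirect effect	unmapped
missing interaction	unmapped
binding/association	unmapped
dissociation	unmapped
reaction	unmapped
ubiquitination	unmapped
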