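acting_type	target_type	meta_relation
gene/protein	gene/protein	increase
gene/protein	biological process	increase
gene/protein	drug	increase
gene/protein	metabolite	increase
gene/protein	disease	increase
drug	gene/protein	increase
drug	biological process	increase
drug	disease	increase
disease	gene/protein	increase
disease	biological process	increase
disease	metabolite	increase
disease	disease	increase
biological process	gene/protein	increase
biological process	biological process	increase
biological process	metabolite	increase
biological process	disease	increase
gene/protein	gene/protein	decrease
gene/protein	biological process	decrease
gene/protein	metabolite	decrease
gene/protein	drug	decrease
gene/protein	disease	decrease
drug	gene/protein	decrease
drug	biological process	decrease
drug	disease	decrease
disease	gene/protein	decrease
disease	biological process	decrease
disease	metabolite	decrease
disease	disease	decrease
biological process	gene/protein	decrease
biological process	biological process	decrease
biological process	metabolite	decrease
biological process	drug	decrease
biological process	disease	decrease
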