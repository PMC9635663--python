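# Synonym rules for functional annotation labels, applied after
# lower-casing and whitespace normalization.  First column: regular
# expression matched against the whole label; second column: canonical
# label.  The first matching rule wins.  Extend freely: real annotation
# sets carry many more spelling variants than this starter set.
terminase,? large subunit	terminase, large subunit
terl	terminase, large subunit
large terminase( subunit)?	terminase, large subunit
terminase,? small subunit	terminase, small subunit
ters	terminase, small subunit
small terminase( subunit)?	terminase, small subunit
(head[ -]to[ -]tail )?connector( protein)?	head-to-tail connector
head[ -]to[ -]tail adaptor	head-to-tail connector
portal( protein)?	portal
major capsid( protein)?	major capsid protein
mcp	major capsid protein
minor tail( protein)?	minor tail protein
tail assembly chaperone( protein)?	tail assembly chaperone
lysin ?b	lysin B
lysb	lysin B
lysin ?a	lysin A
lysa	lysin A
endolysin	lysin A
holin( protein)?	holin
integrase( protein)?	integrase
excise	excisionase
excisionase	excisionase
immunity repressor( protein)?	immunity repressor
repressor	immunity repressor
dna pol(ymerase)? ?i?	DNA polymerase I
dna primase( protein)?	DNA primase
dna helicase( protein)?	DNA helicase
scaffold(ing)?( protein)?	scaffolding protein
(hypothetical|conserved hypothetical|putative|unknown|uncharacterized|predicted)( (protein|function))?	hypothetical protein
(no known function|nkf|unknown function|phage protein|orf\d*|gp\d+)	hypothetical protein
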