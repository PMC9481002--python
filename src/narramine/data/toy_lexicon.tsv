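word	code	polarity
joy	PA	positive
delight	PA	positive
comfort	PE	positive
ease	PE	positive
respect	PD	positive
admire	PD	positive
praise	PH	positive
applaud	PH	positive
trust	PG	positive
faith	PG	positive
like	PB	positive
fond	PB	positive
wish	PK	positive
hope	PK	positive
angry	NA	negative
furious	NA	negative
upset	NB	negative
sorrow	NB	negative
disappointed	NJ	negative
letdown	NJ	negative
guilty	NH	negative
remorse	NH	negative
grief	PF	negative
mourn	PF	negative
panic	NI	negative
nervous	NI	negative
dread	NC	negative
nervous	NC	negative
shame	NG	negative
embarrassed	NG	negative
depressed	NE	negative
gloomy	NE	negative
hate	ND	negative
loathe	ND	negative
criticize	NN	negative
blame	NN	negative
envious	NK	negative
jealous	NK	negative
suspect	NL	negative
doubt	NL	negative
surprise	PC	positive
startled	PC	negative
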