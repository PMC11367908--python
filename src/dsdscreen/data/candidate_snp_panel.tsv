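gene	note
IFITM1	primordial germ cell migration/development; WNT/beta-catenin target; 8 candidate SNPs incl. c.218T>C
LHR	Leydig cell hypoplasia with male pseudohermaphroditism
ZFPM2	46,XY sex reversal 9
HSD17B6	steroid hormone synthesis enzyme
WNT4	female reproductive development; 46,XX DSD (SERKAL syndrome)
BMP8B	primordial germ cell formation; primary ovarian insufficiency
POU5F1	embryonic development; germ cell tumours
AMHR2	persistent Muellerian duct syndrome / DSD
NOBOX	early folliculogenesis; premature ovarian failure 5; incl. c.1043C>G
LHX9	gonadal development; 46,XY DSD
CFTR	obstructive azoospermia spectrum
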