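species_code	kingdom	clade
osa	plant	monocot
zma	plant	monocot
sbi	plant	monocot
ath	plant	dicot
gma	plant	dicot
bna	plant	dicot
lsa	plant	dicot
mtr	plant	dicot
hsa	animal	not_applicable
mmu	animal	not_applicable
ssc	animal	not_applicable
gga	animal	not_applicable
api	animal	not_applicable
bmo	animal	not_applicable
dme	animal	not_applicable
hze	animal	not_applicable
sfr	animal	not_applicable
dvv	animal	not_applicable
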