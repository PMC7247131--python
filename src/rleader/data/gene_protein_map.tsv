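# Gene symbol -> product class and r-protein name (bacterial nomenclature;
# eL15/S3ae are the eukaryotic/archaeal proteins).  Non-ribosomal genes that
# commonly appear inside r-protein operons are listed as "other".
# columns: symbol	product_class	protein
rplA	r-protein	L1
rplB	r-protein	L2
rplC	r-protein	L3
rplD	r-protein	L4
rplE	r-protein	L5
rplF	r-protein	L6
rplI	r-protein	L9
rplJ	r-protein	L10
rplK	r-protein	L11
rplL	r-protein	L7/L12
rplM	r-protein	L13
rplN	r-protein	L14
rplO	r-protein	L15
rplP	r-protein	L16
rplQ	r-protein	L17
rplR	r-protein	L18
rplS	r-protein	L19
rplT	r-protein	L20
rplU	r-protein	L21
rplV	r-protein	L22
rplW	r-protein	L23
rplX	r-protein	L24
rplY	r-protein	L25
rpmA	r-protein	L27
rpmB	r-protein	L28
rpmC	r-protein	L29
rpmD	r-protein	L30
rpmE	r-protein	L31
rpmF	r-protein	L32
rpmG	r-protein	L33
rpmH	r-protein	L34
rpmI	r-protein	L35
rpmJ	r-protein	L36
rpsA	r-protein	S1
rpsB	r-protein	S2
rpsC	r-protein	S3
rpsD	r-protein	S4
rpsE	r-protein	S5
rpsF	r-protein	S6
rpsG	r-protein	S7
rpsH	r-protein	S8
rpsI	r-protein	S9
rpsJ	r-protein	S10
rpsK	r-protein	S11
rpsL	r-protein	S12
rpsM	r-protein	S13
rpsN	r-protein	S14
rpsO	r-protein	S15
rpsP	r-protein	S16
rpsQ	r-protein	S17
rpsR	r-protein	S18
rpsS	r-protein	S19
rpsT	r-protein	S20
rpsU	r-protein	S21
rpl15e	r-protein	eL15
rps3ae	r-protein	S3ae
rpoA	other
rpoB	other
rpoC	other
rimM	other
rimP	other
ssbA	other
ssb	other
recJ	other
infC	other
trmD	other
nusA	other
secY	other
adk	other
map	other
tsf	other
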