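# Curated reference set of 20 novel candidate r-leader motifs used to
# validate the ligand-inference procedure and as a worked example.
# columns:
#   motif_id          short slug (ligand + lineage)
#   lineage           taxon in which the motif occurs
#   domain            bacteria | archaea
#   ligand            most likely r-protein ligand (joint name for dimers)
#   basis             Only | Prior | Closest
#   at_sign           1 when the Prior call rests on a ligand established
#                     within the same screening run (the "@" case), else 0
#   rating            Y (likely candidate) | ? (borderline)
#   rrna_similarity   1 when the leader plausibly resembles the ligand's
#                     rRNA binding site, else 0
#   regulated_genes   consensus operon, transcription order, comma-separated
#   often_extended    minority genes that sometimes extend the operon
#   extendable        1 when the operon can often be extended by further,
#                     unlisted genes
#   overrides         per-motif symbol=protein corrections applied to the
#                     gene->protein map before inference (records an
#                     annotation inconsistency as printed in the source
#                     table: the L20 row lists rpsT, conventionally S20,
#                     yet assigns ligand L20)
motif_id	lineage	domain	ligand	basis	at_sign	rating	rrna_similarity	regulated_genes	often_extended	extendable	overrides
L2-Alphaproteobacteria	Alphaproteobacteria	bacteria	L2	Closest	0	?	0	rplB,rpsS,rplV,rpsC
L4-Archaeoglobi	Archaeoglobi	archaea	L4	Prior	0	?	0	rplC,rplD,rplW,rplB		1
L13-Bacteroidia	Bacteroidia	bacteria	L13	Prior	0	Y	0	rplM,rpsI	rpsB
eL15-Euryarchaeota	Euryarchaeota	archaea	eL15	Only	0	Y	1	rpl15e
L17-ActinoProteobacteria	Actino- and Proteobacteria	bacteria	L17	Only	0	Y	0	rplQ
L20-Deltaproteobacteria	Deltaproteobacteria	bacteria	L20	Only	0	Y	1	rpsT			rpsT=L20
L31-Actinobacteria	Actinobacteria	bacteria	L31	Only	0	Y	0	rpmE
L31-Coriobacteria	Coriobacteria	bacteria	L31	Only	0	Y	0	rpmE
L31-Corynebacteriaceae	Corynebacteriaceae	bacteria	L31	Prior	1	Y	0	rpmE,rpmF
L31-Firmicutes	Firmicutes	bacteria	L31	Only	0	Y	0	rpmE
L31-Gammaproteobacteria	Gammaproteobacteria	bacteria	L31	Only	0	Y	0	rpmE
S4-Bacteroidia	Bacteroidia	bacteria	S4	Prior	0	Y	0	rpsD,rpoA,rplQ
S4-Clostridia	Clostridia	bacteria	S4	Prior	0	Y	0	rpsM,rpsK,rpsD,rpoA,rplQ
S4-Flavobacteria	Flavobacteria	bacteria	S4	Prior	0	Y	0	rpsD,rpoA,rplQ
S4-Fusobacteriales	Fusobacteriales	bacteria	S4	Prior	0	Y	1	rpsM,rpsK,rpsD,rpoA,rplQ
S6S18-Chlorobi	Chlorobi	bacteria	S6:S18	Prior	0	Y	0	rpsF,ssbA,rpsR,rplI
S15-Flavobacteria	Flavobacteria	bacteria	S15	Only	0	?	0	rpsO
S15-Halobacteria	Halobacteria	archaea	S15	Prior	0	Y	1	rpsO,rps3ae	recJ
S15-Methanomicrobia	Methanomicrobia	archaea	S15	Prior	0	Y	1	rpsO,rps3ae	recJ
S16-Flavobacteria	Flavobacteria	bacteria	S16	Only	0	Y	0	rpsP,rimM
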