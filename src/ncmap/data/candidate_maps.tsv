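peptide	coordinates	region	n_reads	alteration	canonical	af_percent	ms_replicates	ms_intensity	gene_fpkm	pool
NKKNEGWLSKP	chr19:40559969-40560003	intron	10	WT	Non-canonical	100	1	NA	50.32	1
EMKPFIPI	chrX:104994035-104994060	extragenic	10	WT	Non-canonical	100	1	11750000	NA	1
FRGLTETTSSL	chr8:34821561-34821595	extragenic	12	WT	Non-canonical	100	1	NA	NA	1
FLRRCCLARYE	chrX:142351611-142351618 chrX:142390305-142390331	utr5	10	WT	Non-canonical	100	1	NA	26.06	1
LKIAWLREICL	chr9:14546274-14546308	utr3	16	SNV	Non-canonical	15.9574	1	NA	23.57	1
YRRFSFEG	chr7:118853174-118853202	cds	12	SNV	Non-canonical	14.4144	2	15288667	14.72	2
VKMPDAPR	chr12:105662622-105662648	cds	11	SNV	Non-canonical	18.5185	1	16421000	5.59	2
CASARCSPCLT	chr2:34870760-34870794	cds	15	SNV	Non-canonical	12.973	1	NA	39.25	2
AEKLKRAAEKD	chrX:136085159-136085193	utr5	12	WT	Non-canonical	100	1	NA	5.46	2
HKKPQPVPRAH	chr6:120482825-120482859	utr3	15	SNV	Non-canonical	15.8273	1	NA	9.42	2
RQWERTVKNKQ	chr5:67621541-67621575	utr3	11	WT	Non-canonical	100	1	NA	1.47	2
ELRLRHIAWAL	chr11:96712585-96712619	intron	14	WT	Non-canonical	100	1	NA	0.82	2
ITINPIKSMLF	chr16:30341231-30341265	cds	17	WT	Non-canonical	100	1	NA	43.64	3
IFPSIGDLALS	chr14:101918019-101918044 chr14:101918612-101918620	cds	14	WT	Non-canonical	100	1	NA	78.13	3
PSAFILIRKLG	chr7:45013466-45013500	cds	12	SNV	Non-canonical	16.7883	1	NA	38.55	3
PVVCKSQLAHG	chr1:164050176-164050187 chr1:164050644-164050666	cds	21	WT	Non-canonical	100	1	NA	20.21	3
VLVMFLLGKLP	chr4:82804025-82804058	utr3	18	WT	Non-canonical	100	1	NA	17.02	3
EPHSVTELKLE	chrX:136079187-136079221	intron	11	WT	Non-canonical	100	1	NA	5.46	3
SAVWTDLKMTP	chr1:153453947-153453981	extragenic	10	WT	Non-canonical	100	1	NA	NA	3
KCFSVISLYFE	chr5:67732187-67732221	cds	10	WT	Non-canonical	100	1	NA	1.47	3
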