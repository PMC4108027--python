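family	arabidopsis	physcomitrella	ancestral
udp_rhamnose_synthase	4	6	1
udp_glca_epimerase	5	9	1
gaut	15	8	3
gatl	10	3	1
galactan_galactosyltransferase	3	4	1
rgii_xylosyltransferase	4	1	1
rgi_arabinosyltransferase	2	0	ND
xga_xylosyltransferase	2	0	ND
hg_methyltransferase	6	3	2
pectin_methylesterase	66	14	5
pmei	2	0	ND
polygalacturonase	67	10	5
pgip	2	0	ND
pectate_lyase_like	26	7	2
pectin_acetylesterase	11	1	1
pectin_acetyltransferase	4	3	1
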