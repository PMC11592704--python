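variant	chrom	pos	hgvs_c	hgvs_p	dbsnp	acmg_class
V1	22	28694066	c.1427C>T	p.Thr476Met	rs142763740	Low risk-LP
V2	22	28725099	c.470T>C	p.Ile157Thr	rs17879961	Low risk-LP
V3	22	28709998	c.846+4_846+7del		rs764884641	LP
V4	22	28699929	c.917G>C	p.Gly306Ala	rs587780192	LP
V5	22	28719416	c.660_661delCA	p.Ile221Hisfs*23		LP
V6	22	28734432	c.290G>A	p.Trp97Ter		LP
V7	22	28695739	c.1100del	p.Thr367Metfs*15	rs555607708	P
V8	22	28695737	c.1232G>A	p.Trp411Ter	rs371418985	P
V9	22	28734664	c.58C>T	p.Gln20Ter	rs536907995	P
V10	22	28725070	c.499G>A	p.Gly167Arg	rs72552322	P
V11	22	28725278	c.409C>T	p.Arg137Ter	rs730881701	P
V12	22	28696924	c.1072C>T	p.Gln358Ter	rs878854909	P
V13	22	28703567	c.847-1G>A		rs878854926	P
V14	22	28711907	c.792+2T>A			P
V15	22	28694130	c.1376-13A>G		rs1064793330	VUS
V16	22	28725106	c.463T>C	p.Ser155Pro	rs1175278074	VUS
V17	22	28696929	c.1067C>T	p.Ser356Leu	rs121908703	VUS
V18	22	28695768	c.1201A>G	p.Thr401Ala	rs121908704	VUS
V19	22	28694072	c.1421G>A	p.Arg474His	rs121908706	VUS
V20	22	28695726	c.1243G>A	p.Val415Ile	rs1601721900	VUS
V21	22	28695190	c.1312G>T	p.Asp438Tyr	rs200050883	VUS
V22	22	28725277	c.410G>A	p.Arg137Gln	rs368570187	VUS
V23	22	28687968	c.1561C>T	p.Arg521Trp	rs533475838	VUS
V24	22	28725089	c.480A>G	p.Ile160Met	rs575910805	VUS
V25	22	28687973	c.1556G>T	p.Arg519Leu	rs587780180	VUS
V26	22	28734461	c.246_260delCCAAGAACCTGAGGA	p.Asp82_Glu86del	rs587780181	VUS
V27	22	28703507	c.906A>C	p.Glu302Asp	rs587780190	VUS
V28	22	28725118	c.451G>T	p.Gly151Cys	rs587781377	VUS
V29	22	28696943	c.1053G>T	p.Glu351Asp	rs587782268	VUS
V30	22	28703509	c.904G>A	p.Glu302Lys	rs587782460	VUS
V31	22	28689167	c.1510G>C	p.Glu504Gln	rs587782489	VUS
V32	22	28724974	c.592+3A>T		rs587782849	VUS
V33	22	28734552	c.170C>G	p.Ser57Cys	rs730881695	VUS
V34	22	28725020	c.549G>C	p.Leu183Phe	rs745646057	VUS
V35	22	28711965	c.736G>C	p.Val246Leu	rs748504161	VUS
V36	22	28687894	c.*2dupC		rs749257861	VUS
V37	22	28695743	c.1226A>T	p.Asp409Val	rs761095543	VUS
V38	22	28725031	c.538C>T	p.Arg180Cys	rs77130927	VUS
V39	22	28712015	c.686G>A	p.Gly229Asp	rs778212685	VUS
V40	22	28725265	c.1118A>G	p.Lys373Arg	rs786202446	VUS
V41	22	28725265	c.422A>C	p.Lys141Thr	rs786203192	VUS
V42	22	28703566	c.847C>T	p.Pro283Ser	rs1555917036	VUS
V43	22	28734441	c.281C>T	p.Ala94Val		VUS
V44	22	28725130	c.445-6T>A			VUS
V45	22	28695858	c.1110del	p.Thr367Mfs*15		VUS
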