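# Published PAS-SNP catalogue rows for the Fat/Lean mouse selection lines:
# common genes (both lines), obesity-related genes and APA-related genes.
# Columns mirror the pipeline's pas_snps.tsv report layout.
mouse_line	variant_id	location	gene_symbol	apa_id	type	pas	pas_alt	consequence
Fat	rs252244088	11:58980172	Trim11	11:58980198:+	IN	AATAAA	AATACA	MA → LA motif
Lean	rs29473166	11:58979030	Trim11	11:58979039:+	IN	TATAAA	TGTAAA	Loss
Fat	rs27517013	4:129219177	Yars	4:129219188:+	TE	CATAAA	CATAAG	Loss
Lean	rs3167104	4:129197453	Yars	4:129197470:+	IN	AATATA	AATACA	MA → LA motif
Fat	rs259336677	9:105077523	Mrpl3	9:105077566:+	TE	AAGAAA	AAGAAG	Loss
Fat	rs238373229	9:105077540	Mrpl3	9:105077566:+	TE	AATATA	AATAAA	LA → MA motif
Lean	rs50804946	9:105077439	Mrpl3	9:105077462:+	TE	TATAAA	TATAAG	Loss
Fat	rs581302908	1:34809203	Arhgef4	1:34809218:+	TE	AATAAA	AATAGA	MA → LA motif
Lean	rs46757124	1:34691617	Arhgef4	1:34691633:+	IN	AATAAA	AGTAAA	MA → LA motif
Fat	rs13459552	7:96910302	Tenm4	7:96910339:+	TE	AGTAAA	AATAAA	LA → MA motif
Lean	rs51720083	7:96237422	Tenm4	7:96237473:+	IN	ATTAAA	ATCAAA	Loss
Fat	rs29969996	6:53639550	Creb5	6:53639571:+	IN	AATGAA	AATAAA	LA → MA motif
Lean	rs29943631	6:53297572	Creb5	6:53297588:+	IN	ATTAAA	ATTAAC	Loss
Fat	rs220155151	1:178956075	Smyd3	1:178956062:-	TE	AATACA	AATATA	LA → MA motif
Fat	rs241932144	1:178957273	Smyd3	1:178957259:-	TE	ATTAAA	ATAAAA	Loss
Fat	rs236503723	1:179168920	Smyd3	1:179168907:-	IN	ATTAAA	ATTATA	MA → LA motif
Fat	rs235763389	1:179508325	Smyd3	1:179508286:-	TE	ATTAAA	ATTTAA	Loss
Lean	rs48210465	1:179394422	Smyd3	1:179394400:-	IN	AATACA	AATATA	LA → MA motif
Fat	rs30706788	3:84809818	Gm37240	3:84809806:-	IN	ATTAAA	GTTAAA	Loss
Lean	rs258005769	3:85755470	Gm37240	3:85755450:-	IN	AGTAAA	AATAAA	LA → MA motif
Lean	rs30399416	3:85789619	Gm37240	3:85789600:-	IN	ACTAAA	ACCAAA	Loss
Fat	rs32753534	7:45971020	Abcc6	7:45970994:-	IN	ATTACA	ATTAAA	LA → MA motif
Fat	rs32689441	8:11302646	Col4a1	8:11302636:-	IN	AAGAAA	AAGGAA	Loss
Fat	rs47853609	5:22926791	Lhfpl3	5:22926806:+	IN	AATGAA	AATGGA	Loss
Fat	rs48552886	5:22926797	Lhfpl3	5:22926806:+	IN	GATAAA	GATGAA	Loss
Fat	rs587469149	18:12210261	Npc1	18:12210214:-	IN	AATAGA	TATAGA	Loss
Lean	rs243180722	16:41720764	Lsamp	16:41720799:+	IN	AATATA	AATATT	Loss
Lean	rs38383450	5:51561938	Ppargc1a	5:51561914:-	IN	TATAAA	AATAAA	LA → MA motif
Fat	rs29182020	12:73176649	Mnat1	12:73176668:+	IN	AATAAA	AATTAA	Loss
Fat	rs579356626	8:94873520	Polr2c	8:94873526:+	TE	AATAAA	AATAAG	MA → LA motif
Lean	rs33836529	6:28799697	Snd1	6:28799710:+	IN	AATAAA	AATACA	MA → LA motif
Lean	rs33289253	15:44436556	Eny2	15:44436573:+	TE	AATAAT	AATATT	Loss
Lean	rs227466545	4:155889082	Ints11	4:155889098:+	TE	AATAAA	AATACA	MA → LA motif
Lean	rs37020130	5:52159959	Dhx15	5:52159940:-	IN	AATAAA	AGTAAA	MA → LA motif
Lean	rs33250559	15:43268200	Eif3e	15:43268181:-	IN	AGTAAA	AGTGAA	Loss
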