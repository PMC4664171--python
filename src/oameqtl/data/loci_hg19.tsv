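locus_id	snp_id	chromosome	position	major_allele	minor_allele	risk_allele	ld_start	ld_end	stratum	proxy_snp	proxy_r2
locus01	rs6976	3	52728804	C	T	T	.	.	knees_and_hips	.	.
locus02	rs12107036	3	191082854	G	A	A	.	.	female_knees	.	.
locus03	rs10948172	6	44777691	A	G	G	44683049	45349877	males	.	.
locus04	rs9350591	6	76298247	C	T	T	.	.	hips	rs7756065	1.0
locus05	rs3815148	7	106938420	A	C	C	.	.	knees	rs1548524	1.0
locus06	rs4836732	9	118306516	T	C	C	.	.	female_hips	.	.
locus07	rs10492367	12	27906237	G	T	T	.	.	hips	rs10843013	1.0
locus08	rs835487	12	103584897	A	G	G	.	.	hips	.	.
locus09	rs11842874	13	113694259	A	G	G	.	.	knees_and_hips	.	.
locus10	rs225014	14	80669330	T	C	C	.	.	hips	.	.
locus11	rs945006	14	102029277	T	G	G	.	.	knees_and_hips	.	.
locus12	rs3204689	15	58246802	C	G	C	.	.	hands	.	.
locus13	rs8044769	16	53839135	C	T	T	.	.	females	.	.
locus14	rs12982744	19	2177193	C	G	G	.	.	male_hips	.	.
locus15	rs6094710	20	46095649	G	A	A	.	.	hips	.	.
locus16	rs143383	20	34025983	T	C	T	.	.	knees_and_hips	rs6087704	0.93
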