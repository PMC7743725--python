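# Polymorphic canonical microRNA target sites with high population
# differentiation (Fst > 0.6) in the 1000 Genomes superpopulations.
# mirna: representative microRNA of the seed family; target_state: 'a' if the
# target allele is ancestral, 'd' if derived; EAS..SAS: target-allele
# frequency per superpopulation; ALL: pooled target-allele frequency.
mirna	gene	snp_id	target_state	EAS	AMR	AFR	EUR	SAS	ALL	fst
miR-92a-3p	PTK6	rs186332	d	0.964	0.873	0.047	0.928	0.593	0.630	0.849
miR-518d-5p	MTAP	rs7868374	a	0.008	0.048	0.684	0.005	0.118	0.213	0.824
let-7a-5p	MTAP	rs7875199	a	0.054	0.058	0.796	0.007	0.129	0.256	0.800
miR-202-5p	ATP1A1	rs1885802	a	0.043	0.127	0.811	0.034	0.045	0.256	0.791
miR-1180-3p	MYEF2	rs2470102	a	0.753	0.339	0.925	0.006	0.272	0.497	0.773
miR-24-3p	SCN2B	rs624328	d	0.941	0.891	0.252	0.951	0.967	0.760	0.767
miR-21-3p	C4orf46	rs11544037	a	0.025	0.262	0.854	0.130	0.169	0.326	0.745
miR-130a-3p	SLC30A9	rs12511999	a	0.049	0.236	0.913	0.250	0.222	0.377	0.730
miR-513a-3p	TCERG1	rs3822506	d	0.718	0.117	0.033	0.092	0.220	0.231	0.722
miR-1296-5p	BCL7C	rs11864054	a	0.088	0.455	0.976	0.618	0.841	0.628	0.714
miR-192-5p	C12orf65	rs1533703	a	0.998	0.726	0.149	0.769	0.795	0.651	0.707
miR-221-5p	FZR1	rs10155	d	0.798	0.473	0.015	0.294	0.302	0.348	0.692
miR-7-5p	ENAM	rs7665492	a	0.023	0.133	0.744	0.058	0.055	0.242	0.685
miR-514a-3p	EXOC5	rs3742577	a	0.114	0.125	0.845	0.119	0.121	0.311	0.683
miR-769-5p	ARIH1	rs11072379	a	0.235	0.212	0.894	0.095	0.097	0.351	0.674
miR-769-5p	MPHOSPH9	rs1727314	a	0.977	0.726	0.142	0.768	0.741	0.634	0.668
miR-381-3p	PLXNA4	rs6968754	a	0.166	0.445	0.920	0.285	0.361	0.466	0.658
miR-520d-3p	UBE2Q1	rs11265634	a	0.098	0.221	0.870	0.186	0.199	0.356	0.649
miR-513c-5p	CYB5R4	rs6912739	d	1.000	0.932	0.381	0.954	0.994	0.818	0.646
miR-335-3p	PLCB2	rs4257181	a	0.446	0.899	0.987	0.991	0.911	0.853	0.643
miR-19b-3p	TRNT1	rs60884103	d	0.699	0.242	0.054	0.024	0.360	0.264	0.643
miR-22-3p	OPLAH	rs28475718	d	1.000	0.957	0.437	0.989	0.969	0.838	0.641
miR-335-3p	ANGEL2	rs41277158	a	0.997	0.950	0.412	0.963	0.949	0.821	0.641
miR-103a-3p	HEXA	rs11629508	d	0.774	0.839	0.179	0.946	0.943	0.694	0.631
miR-34a-5p	CDPF1	rs1053332	a	0.001	0.169	0.746	0.194	0.082	0.276	0.631
miR-144-3p	CFAP61	rs1410937	a	1.000	0.954	0.412	1.000	1.000	0.839	0.626
miR-144-5p	RSU1	rs6977	d	0.895	0.921	0.275	0.982	0.932	0.760	0.625
miR-223-3p	PCDH15	rs11003862	d	0.055	0.591	0.731	0.764	0.440	0.526	0.625
miR-145-5p	C3orf85	rs56027044	d	0.164	0.392	0.879	0.590	0.441	0.524	0.622
miR-509-5p	PKDREJ	rs6007729	a	1.000	0.937	0.421	0.963	0.964	0.825	0.621
miR-197-3p	GP2	rs12444232	d	0.682	0.157	0.032	0.047	0.190	0.214	0.616
miR-200b-3p	PCDH15	rs11003861	a	0.810	0.339	0.048	0.179	0.454	0.347	0.612
miR-124-3p	CPSF4	rs1043466	d	0.660	0.716	0.055	0.833	0.618	0.535	0.608
miR-381-3p	INAFM2	rs2289333	d	0.554	0.308	0.007	0.090	0.153	0.204	0.607
miR-377-3p	OGDHL	rs6816	a	0.105	0.529	0.933	0.553	0.582	0.566	0.607
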