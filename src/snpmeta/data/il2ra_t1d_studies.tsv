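study_id	label	year	country	ancestry	snp	design	case_counts	control_counts	maf_cases	maf_controls	reported_or	ci_low	ci_high	orientation	n_cases	n_controls
lowe2007_s1	Lowe et al. set 1	2007	UK	European	rs11594656	case_control	1744/994/136	1385/956/143	0.213	0.244	0.84	0.76	0.92	minor	2965	2548
lowe2007_s2	Lowe et al. set 2	2007	UK	European	rs11594656	case_control	3186/1827/246	3850/2548/411	0.220	0.247	0.87	0.81	0.92	minor	5259	6809
lowe2007_s1	Lowe et al. set 1	2007	UK	European	rs41295061	case_control	2543/344/20	2002/457/35	0.065	0.103	0.61	0.53	0.70	minor	2965	2548
lowe2007_s2	Lowe et al. set 2	2007	UK	European	rs41295061	case_control	4609/675/28	5520/1250/85	0.069	0.104	0.65	0.59	0.71	minor	5312	6855
kawasaki2009	Kawasaki et al.	2009	Japan	Asian	rs11594656	case_control	836/43/2	570/35/1	0.027	0.031	0.91	0.59	1.41	minor	882	606
kawasaki2009	Kawasaki et al.	2009	Japan	Asian	rs3118470	case_control	206/427/239	159/298/135	0.519	0.479	1.18	1.01	1.35	minor	872	592
kawasaki2009	Kawasaki et al.	2009	Japan	Asian	rs706778	case_control	307/421/149	170/309/123	0.410	0.461	1.23	1.06	1.43	major	877	602
maier2009	Maier et al.	2009	UK/US	European	rs2104286	case_control	ND	ND	ND	ND	0.80	0.76	0.85	minor	6425	6862
grant2009_s1	Grant et al. set 1	2009	UK	European	rs3118470	case_control	ND	ND	0.361	0.319	1.21	1.11	1.31	minor	2000	3000
grant2009_s2	Grant et al. set 2	2009	US	European	rs3118470	case_control	ND	ND	0.365	0.306	1.30	1.12	1.52	minor	563	1146
aminkeng2010	Aminkeng et al.	2010	Belgium	European	rs41295061	case_control	ND	ND	0.054	0.084	0.63	0.52	0.75	minor	1954	2082
klinker2010	Klinker et al.	2010	Finland	European	rs11594656	case_control	ND	ND	ND	ND	0.98	0.82	1.17	minor	591	1538
klinker2010	Klinker et al.	2010	Finland	European	rs41295061	case_control	ND	ND	ND	ND	0.95	0.74	1.25	minor	591	1538
yamashita2011	Yamashita et al.	2011	Japan	Asian	rs706778	case_control	ND	ND	ND	ND	1.2	1.0	1.4	minor	790	953
espino2011	Espino-Paisan et al.	2011	Spain	European	rs11594656	case_control	205/179/46	375/330/86	0.315	0.317	0.99	0.82	1.19	minor	430	791
espino2011	Espino-Paisan et al.	2011	Spain	European	rs2104286	case_control	277/135/18	488/268/42	0.199	0.221	0.88	0.71	1.08	minor	430	798
espino2011	Espino-Paisan et al.	2011	Spain	European	rs41295061	case_control	393/35/3	704/105/2	0.048	0.067	0.69	0.47	1.02	minor	431	811
kisand2012	Kisand et al.	2012	Estonia	European	rs706778	case_control	ND	ND	0.47	0.45	1.08	0.81	1.44	minor	229	154
fichna2012	Fichna et al.	2012	Poland	European	rs11594656	case_control	273/155/17	373/248/50	0.212	0.259	0.77	0.63	0.94	minor	445	671
fichna2012	Fichna et al.	2012	Poland	European	rs2104286	case_control	312/123/10	457/187/27	0.161	0.180	0.89	0.72	1.09	minor	445	671
fichna2012	Fichna et al.	2012	Poland	European	rs3118470	case_control	153/217/75	283/306/72	0.412	0.335	1.30	1.09	1.55	minor	445	671
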