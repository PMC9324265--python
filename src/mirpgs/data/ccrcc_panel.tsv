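gene_label	chrom	pos	rsid	effect_allele	other_allele	eaf_case	eaf_control
AGO1	1	36380133	rs595055	T	C	0.26	0.30
DDX20	1	112308953	rs197412	T	C	0.47	0.49
DROSHA	5	31435627	rs4867329	A	C	0.46	0.49
C5orf22	5	31532789	rs17409893	A	G	0.31	0.32
XPO5	6	43492578	rs2257082	G	A	0.33	0.33
AGO2	8	141555862	rs3864659	A	C	0.12	0.14
AGO2	8	141594460	rs7005286	T	C	0.23	0.21
MIR196A2	12	54385599	rs11614913	T	C	0.38	0.37
PIWIL1	12	130852174	rs11060845	G	T	0.07	0.11
RAN	12	131355546	rs3809142	C	T	0.11	0.16
DICER1	14	95554142	rs1057035	C	T	0.44	0.29
DICER1	14	95556747	rs13078	T	A	0.13	0.17
GEMIN4	17	649232	rs3744741	C	T	0.15	0.18
GEMIN4	17	649505	rs4968104	T	A	0.21	0.22
GEMIN4	17	649935	rs2740348	G	C	0.19	0.17
MIR423	17	28444183	rs6505162	A	C	0.50	0.46
DDX5	17	62502435	rs1991401	G	A	0.44	0.38
MIR27A	19	13947292	rs895819	T	C	0.34	0.35
DGCR8	22	20098544	rs417309	G	A	0.08	0.10
DGCR8	22	20098582	rs720012	A	G	0.24	0.20
DGCR8	22	20098882	rs720014	C	T	0.24	0.21
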